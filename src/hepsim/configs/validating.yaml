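# Parameterization of the validating experiments.
# Culture (ISHC) values that differ between the dose-response and
# time-course experiments live in their own sections; liver (ISL) values
# that differ between control and LPS arms are experiment-design
# parameters and live under isl_protocols.

simulation:
  monteCarloTrials: 16

ishc_dose_response:
  cycleLimit: 2880                # 48 h at 1 cycle = 1 min
  doseTime: 1
  dose_solute: lps
  dosage: [0, 70, 700, 7000, 700000]   # 700 lps objects = 1 ng/ml LPS
  gridWidth: 25
  gridHeight: 25
  kcDensity: 1.0
  hepDensity: 0.0
  enzymesPerCellMin: 4
  enzymesPerCellMax: 8
  inflammatoryThreshold: 1
  cytokineThreshold: 2
  cytokineExponent: 3.0
  measurementCycles: [2880]
  solute_types:
    lps:
      inflammatory: true
      pExitCell: 1.0
      pExitMedia: 0.5
    cytokine:
      pDegrade: 0.01
      pExitCell: 0.01
      pExitMedia: 0.02

ishc_timecourse:
  cycleLimit: 1440                # 24 h at 1 cycle = 1 min
  doseTime: 1
  dose_solute: cytokine
  dosage: 2000
  gridWidth: 25
  gridHeight: 25
  kcDensity: 0.0
  hepDensity: 1.0
  enzymesPerCellMin: 4
  enzymesPerCellMax: 8
  pRemove: 0.05
  delay: 30
  pReplenish: 0.007
  measurementCycles: [0, 720, 1440]    # 0, 12, 24 h
  solute_types:
    lps:
      inflammatory: true
      pExitCell: 1.0
      pExitMedia: 0.1
    cytokine:
      pDegrade: 0.002
      pExitCell: 0.2
      pExitMedia: 0.02
  enzyme_types:
    enzyme:                       # the single culture (generation-1) type
      expressingCellTypes: [hepatocyte]
      metabolic: false
      downRegulated: true

isl:
  pBind: 0.25
  bindCycles: 10
  bindingMode: variable
  inflammatoryThreshold: 3
  cytokineThreshold: 2
  cytokineExponent: 3.0
  delay: 600
  pReplenish: 0.0001
  enzymesPerCellMin: 4
  enzymesPerCellMax: 8
  ecDensity: 0.66
  kcDensity: 0.33
  hepDensity: 0.9
  sampleRatio: 0.00115
  forwardBias: 0.2
  lateralBias: 0.6
  flowRate: 2
  lobule:
    full:      {layers: 5, segmentsPerLayer: 9, coreLength: 10, spaceCircumference: 2}
    compact:   {layers: 5, segmentsPerLayer: 1, coreLength: 10, spaceCircumference: 2}
  solute_types:
    apap:
      bindable: true
      pMetabolize: [0.35, 0.95]
      metabolicProduct: [apap-metabolite]
      sampleRatioFactor: 1.0
    ant:
      bindable: true
      pMetabolize: [0.35, 0.95]
      metabolicProduct: [ant-metabolite]
      sampleRatioFactor: 0.26
    czn:
      bindable: true
      pMetabolize: [0.35, 0.95]
      metabolicProduct: [czn-metabolite]
      sampleRatioFactor: 0.52
      Vd_change: 1.69
    lps:
      inflammatory: true
      pDegrade: 0.0005
      # Required for body-to-lobule transfer.  Endotoxin is eliminated by
      # cellular degradation (pDegrade), not biliary excretion, so a high
      # transfer factor keeps lobule exposure high while body endotoxin
      # still persists for hours, as in rats.
      sampleRatioFactor: 1.0
    cytokine:
      pDegrade: 0.002
    apap-metabolite: {}
    ant-metabolite: {}
    czn-metabolite: {}
  enzyme_types:
    apap-enzyme:
      expressingCellTypes: [hepatocyte]
      acceptedSolutes: [apap]
      metabolic: true
      downRegulated: true
      pRemove: 0.01
      bindExponent: 1.0
    ant-enzyme:
      expressingCellTypes: [hepatocyte]
      acceptedSolutes: [ant]
      metabolic: true
      downRegulated: true
      pRemove: 0.025
      bindExponent: 2.0
    czn-enzyme:
      expressingCellTypes: [hepatocyte]
      acceptedSolutes: [czn]
      metabolic: true
      downRegulated: true
      pRemove: 0.02
      bindExponent: 1.5
    nonspecific:
      expressingCellTypes: [kupffer-cell, endothelial-cell]
      acceptedSolutes: [apap, ant, czn]
      metabolic: false
      downRegulated: false
      bindExponent: 1.0

isl_protocols:
  apap: {cycleLimit_control: 6000,  cycleLimit_lps: 92400,
         lps_dosage: 125000, drug_dosage: 125000, drug_doseTime_lps: 86401}
  ant:  {cycleLimit_control: 18000, cycleLimit_lps: 104400,
         lps_dosage: 125000, drug_dosage: 125000, drug_doseTime_lps: 86401}
  czn:  {cycleLimit_control: 7200,  cycleLimit_lps: 93600,
         lps_dosage: 125000, drug_dosage: 125000, drug_doseTime_lps: 86401}

multidrug:
  drug_dosage_control: 62500
  drug_dosage_lps: 125000
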