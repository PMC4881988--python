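"""The validating experiment protocols and the Monte Carlo trial runner.

Eight shipped protocols: two culture experiments (LPS-cytokine
dose-response; cytokine-driven enzyme time course), six single-drug liver
experiments (three drugs x control/LPS arms), and the two multi-drug
co-administration experiments.  Each protocol is run as seeded Monte Carlo
trials (trial ``i`` uses ``base_seed + i``); reported values are per-trial
series plus cross-trial means and standard deviations.

``scale`` divides dosages and trial counts for desk-scale runs; the
ratio-type readouts (treated/control enzyme and clearance fractions) are
the quantities meaningful at reduced scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import EnzymeType, SoluteType, TypeRegistry, create_cell
from .config import ConfigDocument, ishc_settings_from, isl_settings_from
from .engine import EventQueue, RngStream, SimulationClock
from .ishc import CultureModel
from .isl import LiverModel, apply_vd_change
from .mechanisms import (
    BindingConfig,
    binding_handler,
    metabolism_handler,
    release_bound_pair,
)
from .metrics import auc_and_clearance

__all__ = [
    "TrialResult",
    "AggregateResult",
    "PROTOCOLS",
    "run_protocol",
    "run_dose_response",
    "run_enzyme_timecourse",
    "run_isl_single_drug",
    "run_isl_multidrug",
    "run_binding_falsification",
    "monte_carlo",
]


@dataclass
class TrialResult:
    """One seeded trial: measurement series and scalar readouts."""

    seed: int
    series: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class AggregateResult:
    """Cross-trial mean +/- SD per measurement, plus the raw trials."""

    trials: list[TrialResult]
    mean: dict[str, np.ndarray] = field(default_factory=dict)
    sd: dict[str, np.ndarray] = field(default_factory=dict)
    cycles: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def monte_carlo(run_one, base_seed: int, trials: int) -> AggregateResult:
    """Run ``trials`` seeded replicates and aggregate their series."""
    if trials < 1:
        raise ValueError("need at least one Monte Carlo trial")
    results = [run_one(base_seed + i) for i in range(trials)]
    agg = AggregateResult(trials=results)
    for key in results[0].series:
        stacked = np.array([[v for _, v in r.series[key]] for r in results], float)
        agg.cycles[key] = np.array([c for c, _ in results[0].series[key]])
        agg.mean[key] = stacked.mean(axis=0)
        agg.sd[key] = stacked.std(axis=0, ddof=1) if trials > 1 else np.zeros(
            stacked.shape[1]
        )
    return agg


def _scaled(amount: int, scale: float) -> int:
    return int(round(amount / scale))


# ---------------------------------------------------------------------------
# culture protocols
# ---------------------------------------------------------------------------
def run_dose_response(
    doc: ConfigDocument,
    base_seed: int,
    trials: int | None = None,
    scale: float = 1.0,
) -> dict:
    """LPS dose ladder -> normalized mean cytokine response at 48 h.

    A Kupffer-cell-only culture receives each LPS dose at cycle 1; total
    cytokines are measured at cycle 2880 and the per-dose trial means are
    normalized by the maximum mean.
    """
    sec = doc.ishc_dose_response
    doses = sec.dosage if isinstance(sec.dosage, list) else [sec.dosage]
    trials = trials if trials is not None else max(
        1, _scaled(doc.simulation.monteCarloTrials, scale)
    )
    means, sds, per_dose = [], [], []
    for di, dose in enumerate(doses):

        def run_one(seed: int, _dose=dose) -> TrialResult:
            settings = ishc_settings_from(sec)
            model = CultureModel(settings, RngStream(seed))
            counts = _run_ishc(model, sec, _scaled(_dose, scale))
            return TrialResult(seed=seed, series={"cytokine": counts})

        agg = monte_carlo(run_one, base_seed + 7919 * di, trials)
        final = agg.mean["cytokine"][-1]
        means.append(float(final))
        sds.append(float(agg.sd["cytokine"][-1]))
        per_dose.append(agg)
    means_arr = np.array(means)
    peak = means_arr.max()
    out = {
        "doses": [_scaled(d, scale) for d in doses],
        "mean_cytokines": means,
        "sd_cytokines": sds,
        "trials": trials,
        "aggregates": per_dose,
    }
    if peak <= 0:
        out["normalized"] = None
        out["error"] = "all-zero response; normalization undefined"
    else:
        out["normalized"] = (means_arr / peak).tolist()
    return out


def run_enzyme_timecourse(
    doc: ConfigDocument,
    base_seed: int,
    trials: int | None = None,
    scale: float = 1.0,
    extra_cycles: int = 0,
) -> AggregateResult:
    """Cytokine dose -> normalized culture enzyme levels over 24 h.

    A hepatocyte-only culture receives the cytokine dose at cycle 1;
    total enzymes are measured at the configured cycles (0, 12, 24 h) and
    each trial's series is normalized by its cycle-0 value.  Cytokine
    totals are recorded alongside.  ``extra_cycles`` extends the run past
    the configured limit (recovery studies).
    """
    sec = doc.ishc_timecourse
    trials = trials if trials is not None else max(
        1, _scaled(doc.simulation.monteCarloTrials, scale)
    )
    dose = _scaled(sec.dosage if isinstance(sec.dosage, int) else sec.dosage[0], scale)
    enzyme_name = next(iter(sec.enzyme_types))
    cycles = sorted(set(sec.measurementCycles) | ({sec.cycleLimit + extra_cycles}
                                                  if extra_cycles else set()))

    def run_one(seed: int) -> TrialResult:
        settings = ishc_settings_from(sec)
        model = CultureModel(settings, RngStream(seed))
        enz, cyt = [], []
        for c in cycles:
            _advance_ishc(model, sec, dose, c)
            enz.append((c, model.measure(enzyme_name)))
            cyt.append((c, model.measure("cytokine")))
        base = enz[0][1]
        norm = [(c, v / base if base else float("nan")) for c, v in enz]
        return TrialResult(
            seed=seed,
            series={"enzyme": enz, "enzyme_normalized": norm, "cytokine": cyt},
        )

    return monte_carlo(run_one, base_seed, trials)


def _run_ishc(model: CultureModel, sec, dose: int) -> list[tuple[int, float]]:
    counts = []
    for _ in range(sec.cycleLimit):
        if model.clock.cycle + 1 == sec.doseTime and dose:
            model.dose(sec.dose_solute, dose)
        model.run_cycle()
        if model.clock.cycle in sec.measurementCycles:
            counts.append((model.clock.cycle, model.measure("cytokine")))
    if not counts:
        counts.append((model.clock.cycle, model.measure("cytokine")))
    return counts


def _advance_ishc(model: CultureModel, sec, dose: int, to_cycle: int) -> None:
    while model.clock.cycle < to_cycle:
        if model.clock.cycle + 1 == sec.doseTime and dose:
            model.dose(sec.dose_solute, dose)
        model.run_cycle()


# ---------------------------------------------------------------------------
# liver protocols
# ---------------------------------------------------------------------------
DRUG_ENZYME = {"apap": "apap-enzyme", "ant": "ant-enzyme", "czn": "czn-enzyme"}


def run_isl_single_drug(
    doc: ConfigDocument,
    drug: str,
    arm: str,
    base_seed: int,
    trials: int | None = None,
    scale: float = 1.0,
    lobule: str = "full",
    pre_cycles: int | None = None,
) -> AggregateResult:
    """Control or LPS-pretreatment disposition run for one drug.

    LPS arm: LPS at cycle 1, the drug after the 24 h (86,400-cycle)
    pretreatment; the volume-of-distribution rule divides the dose and the
    body-to-lobule transfer factor of any drug defining ``Vd_change``.
    Control arm: the pretreatment phase is bypassed (nothing in the model
    can change enzyme levels without LPS) and the drug is dosed at cycle 1.
    Body drug counts are measured on an evenly spaced post-dose schedule;
    the drug-matched enzyme total is recorded at the injection cycle.
    """
    return _run_isl(
        doc, [drug], arm, base_seed, trials, scale, lobule, pre_cycles, multi=False
    )


def run_isl_multidrug(
    doc: ConfigDocument,
    arm: str,
    base_seed: int,
    trials: int | None = None,
    scale: float = 1.0,
    lobule: str = "full",
    pre_cycles: int | None = None,
) -> AggregateResult:
    """Co-administration of all three drugs under one parameter set."""
    return _run_isl(
        doc, list(DRUG_ENZYME), arm, base_seed, trials, scale, lobule,
        pre_cycles, multi=True,
    )


def _run_isl(
    doc: ConfigDocument,
    drugs: list[str],
    arm: str,
    base_seed: int,
    trials: int | None,
    scale: float,
    lobule: str,
    pre_cycles: int | None,
    multi: bool,
) -> AggregateResult:
    if arm not in ("control", "lps"):
        raise ValueError("arm must be 'control' or 'lps'")
    for d in drugs:
        if d not in DRUG_ENZYME:
            raise ValueError(f"unknown drug {d!r}")
    trials = trials if trials is not None else max(
        1, _scaled(doc.simulation.monteCarloTrials, scale)
    )

    protos = {d: doc.isl_protocols[d] for d in drugs}
    # post-dose measurement schedule per drug (evenly spaced over the
    # control-arm duration, the window the wet-lab curves span)
    rel_points = {
        d: [
            int(round(p.cycleLimit_control * k / p.measurementPoints))
            for k in range(1, p.measurementPoints + 1)
        ]
        for d, p in protos.items()
    }
    if arm == "lps":
        pre = pre_cycles if pre_cycles is not None else min(
            p.drug_doseTime_lps - 1 for p in protos.values()
        )
    else:
        pre = pre_cycles if pre_cycles is not None else 0
    drug_dose_cycle = pre + 1
    post = max(rel_points[d][-1] for d in drugs)

    def run_one(seed: int) -> TrialResult:
        settings = isl_settings_from(doc.isl, lobule)
        model = LiverModel(settings, RngStream(seed))
        if multi:
            base_amount = (
                doc.multidrug.drug_dosage_lps
                if arm == "lps"
                else doc.multidrug.drug_dosage_control
            )
            amounts = {d: base_amount for d in drugs}
        else:
            amounts = {d: protos[d].drug_dosage for d in drugs}
        doses = {d: _scaled(amounts[d], scale) for d in drugs}
        if arm == "lps":
            for d in drugs:
                st = model.registry.solute(d)
                if st.Vd_change is not None:
                    doses[d], srf = apply_vd_change(
                        doses[d], st.sampleRatioFactor, st.Vd_change
                    )
                    model.srf_override[d] = srf
            lps_amount = _scaled(
                max(protos[d].lps_dosage for d in drugs), scale
            )
            model.dose_body("lps", lps_amount)
        result = TrialResult(seed=seed, meta={"arm": arm, "doses": doses})
        model.run(pre)
        for d in drugs:
            result.scalars[f"enzyme_total_{d}"] = model.measure(DRUG_ENZYME[d])
        for d in drugs:
            model.dose_body(d, doses[d])
        body_series = {d: [(0, float(doses[d]))] for d in drugs}
        for rel in range(1, post + 1):
            model.run_cycle()
            for d in drugs:
                if rel in rel_points[d]:
                    body_series[d].append((rel, float(model.measure(d))))
        for d in drugs:
            result.series[f"body_{d}"] = body_series[d]
            result.scalars[f"dose_{d}"] = float(doses[d])
            times = np.array([t for t, _ in body_series[d]], float)
            counts = np.array([v for _, v in body_series[d]], float)
            try:
                summ = auc_and_clearance(times, counts, doses[d])
                result.scalars[f"half_life_{d}"] = summ.half_life
                result.scalars[f"auc_{d}"] = summ.auc
                result.scalars[f"clearance_{d}"] = summ.clearance
            except ValueError:
                pass
        result.meta["accounting"] = {d: model.accounting(d) for d in drugs}
        return result

    return monte_carlo(run_one, base_seed, trials)


def czn_lps_control_summary(
    doc: ConfigDocument,
    base_seed: int,
    trials: int = 4,
    scale: float = 10.0,
    lobule: str = "compact",
) -> dict[str, float]:
    """Chlorzoxazone LPS-arm readouts as percentages of control.

    Runs the czn control and LPS protocols and reports the drug-matched
    enzyme total at the drug-injection measurement point and the
    dose/AUC clearance (volume-of-distribution-adjusted dose in the LPS
    arm), each as ``100 * LPS / control`` using cross-trial means.
    """
    control = run_isl_single_drug(
        doc, "czn", "control", base_seed, trials=trials, scale=scale,
        lobule=lobule,
    )
    lps = run_isl_single_drug(
        doc, "czn", "lps", base_seed + 1000, trials=trials, scale=scale,
        lobule=lobule,
    )

    def mean_scalar(agg: AggregateResult, key: str) -> float:
        return float(np.mean([t.scalars[key] for t in agg.trials]))

    enz_c = mean_scalar(control, "enzyme_total_czn")
    enz_l = mean_scalar(lps, "enzyme_total_czn")
    cl_c = mean_scalar(control, "clearance_czn")
    cl_l = mean_scalar(lps, "clearance_czn")
    return {
        "enzyme_control": enz_c,
        "enzyme_lps": enz_l,
        "enzyme_pct_of_control": 100.0 * enz_l / enz_c,
        "clearance_control": cl_c,
        "clearance_lps": cl_l,
        "clearance_pct_of_control": 100.0 * cl_l / cl_c,
        "trials": float(trials),
        "scale": float(scale),
    }


# ---------------------------------------------------------------------------
# enzyme-ontology falsification experiment
# ---------------------------------------------------------------------------
def run_binding_falsification(
    mode: str,
    deplete: bool,
    seed: int,
    n_cells: int = 40,
    n_cycles: int = 80,
    supply: int = 2,
    enzymes_min: int = 8,
    enzymes_max: int = 12,
    pBind: float = 0.25,
    pMetabolize: float = 0.65,
) -> int:
    """Metabolite production with or without mid-run enzyme depletion.

    Object-level hepatocytes under constant drug exposure (unbound drug
    topped up to ``supply`` per cell per cycle).  ``deplete`` removes half
    of each cell's enzymes before the run while leaving the basal (initial)
    count untouched — mimicking down-regulation.  Under stepwise binding
    the production rate is insensitive to the depletion (the generation-1
    falsification); under variable binding it drops.  Defaults keep the
    typical regime in which at least one enzyme is unbound, where the
    stepwise insensitivity holds (full occupancy is the rare exception).
    Returns total metabolism events.
    """
    drug = SoluteType(
        name="drug", bindable=True, pMetabolize=pMetabolize, metabolicProduct=()
    )
    enz = EnzymeType(
        name="drug-enzyme",
        expressingCellTypes=("hepatocyte",),
        acceptedSolutes=("drug",),
        metabolic=True,
        downRegulated=False,
        bindExponent=1.0,
    )
    registry = TypeRegistry([drug], [enz])
    rng = RngStream(seed)
    cfg = BindingConfig(mode=mode, pBind=pBind, bindCycles=10)
    clock = SimulationClock(cycle_limit=n_cycles + 1, seconds_per_cycle=1.0)
    queue = EventQueue()
    cells = [
        create_cell("hepatocyte", registry, enzymes_min, enzymes_max, rng)
        for _ in range(n_cells)
    ]
    if deplete:
        for cell in cells:
            enzymes = cell.enzymes["drug-enzyme"]
            del enzymes[: len(enzymes) // 2]
    from .components import Solute

    events = 0
    for _ in range(n_cycles):
        now = clock.cycle + 1
        for ev in queue.pop_due(now):
            solute, enzyme, cell = ev.payload
            release_bound_pair(solute, enzyme, cell)
        for cell in cells:
            unbound = sum(
                1 for s in cell.solutes if s.type.name == "drug" and not s.bound
            )
            for _ in range(max(0, supply - unbound)):
                cell.add_solute(Solute(drug))
        order = rng.permutation(len(cells))
        for ci in order:
            cell = cells[ci]
            if rng.uniform() < 0.5:
                binding_handler(cell, cfg, registry, rng, queue, clock)
                events += metabolism_handler(cell, registry, rng)
            else:
                events += metabolism_handler(cell, registry, rng)
                binding_handler(cell, cfg, registry, rng, queue, clock)
        clock.advance()
    return events


# ---------------------------------------------------------------------------
# protocol registry (CLI surface)
# ---------------------------------------------------------------------------
def _make_isl_runner(drug: str, arm: str):
    def runner(doc, base_seed, trials=None, scale=1.0, lobule="full"):
        return run_isl_single_drug(
            doc, drug, arm, base_seed, trials=trials, scale=scale, lobule=lobule
        )

    return runner


def _make_multi_runner(arm: str):
    def runner(doc, base_seed, trials=None, scale=1.0, lobule="full"):
        return run_isl_multidrug(
            doc, arm, base_seed, trials=trials, scale=scale, lobule=lobule
        )

    return runner


PROTOCOLS = {
    "ishc-dose-response": lambda doc, base_seed, trials=None, scale=1.0, lobule="full":
        run_dose_response(doc, base_seed, trials=trials, scale=scale),
    "ishc-timecourse": lambda doc, base_seed, trials=None, scale=1.0, lobule="full":
        run_enzyme_timecourse(doc, base_seed, trials=trials, scale=scale),
}
for _drug in DRUG_ENZYME:
    for _arm in ("control", "lps"):
        PROTOCOLS[f"isl-{_drug}-{_arm}"] = _make_isl_runner(_drug, _arm)
for _arm in ("control", "lps"):
    PROTOCOLS[f"isl-multidrug-{_arm}"] = _make_multi_runner(_arm)


def run_protocol(name: str, doc: ConfigDocument, base_seed: int, **kwargs):
    if name not in PROTOCOLS:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}"
        )
    return PROTOCOLS[name](doc, base_seed, **kwargs)
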