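"""Diagnostics and derived reports: VPC, goodness-of-fit, attribution.

All reports are pure functions of their inputs (dataset, fit or
population parameters, seed) and return plain tables, so re-running with
identical inputs yields identical files; rendering to figures is left to
the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .design import StudyDesign, build_monkey_study
from .estimate import FitResult, build_variant, prepare_subjects, _predict_subject
from .params import (
    IIV_PARAMETERS,
    DarDistribution,
    PopulationParameters,
    default_dar_distribution,
)
from .simulate import (
    ANALYTE_CODES,
    sample_individual,
    simulate_individual,
    simulate_population,
    subject_rng,
)

__all__ = [
    "VpcResult",
    "vpc",
    "gof_table",
    "attribution_report",
    "dar0_accumulation_report",
]

_PCTL = (5.0, 50.0, 95.0)


@dataclass
class VpcResult:
    """Visual-predictive-check summary.

    ``table`` holds, per arm x analyte x time bin: the observed 5/50/95th
    percentiles of quantifiable values, simulation bands (5/50/95th
    percentiles across replicates of each observed statistic), and the
    observed and simulated BLOQ fractions.
    """

    table: pd.DataFrame
    n_sim: int

    @property
    def has_censoring_panel(self) -> bool:
        return bool((self.table["frac_bloq_obs"] > 0).any())


def _design_subset(dataset: pd.DataFrame, design: StudyDesign) -> StudyDesign:
    """Restrict a design to the arms/sizes present in the dataset."""
    arms = []
    for arm_name, grp in dataset.groupby("ARM", sort=False):
        arm = design.arm(arm_name)
        n = grp["SUBJ"].nunique()
        arms.append(
            type(arm)(
                name=arm.name,
                compound=arm.compound,
                dose_level=arm.dose_level,
                n_subjects=n,
                dose_times=list(arm.dose_times),
                schedule={k: list(v) for k, v in arm.schedule.items()},
                body_weight=arm.body_weight,
            )
        )
    return StudyDesign(arms=arms, dar_distribution=design.dar_distribution, lloq=dict(design.lloq))


def _binned_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Per (ARM, ANALYTE, TIME_H): percentiles of quantifiable DV + BLOQ fraction.

    Time bins with no quantifiable observation are merged into the next
    bin (carrying their BLOQ counts) with a warning.
    """
    rows = []
    for (arm, analyte), grp in df.groupby(["ARM", "ANALYTE"], sort=True):
        pending_n = 0
        pending_bloq = 0
        pending_t = []
        for t, bin_ in grp.groupby("TIME_H", sort=True):
            vals = bin_.loc[bin_["BLOQ"] == 0, "DV"].to_numpy(float)
            n = len(bin_) + pending_n
            n_bloq = int(bin_["BLOQ"].sum()) + pending_bloq
            times = pending_t + [t]
            if vals.size == 0:
                pending_n, pending_bloq, pending_t = n, n_bloq, times
                continue
            if pending_t:
                warnings.warn(
                    f"bin(s) at t={pending_t} for {arm}/{analyte} had no "
                    f"quantifiable values; merged into t={t}"
                )
            q = np.percentile(vals, _PCTL)
            rows.append(
                {
                    "ARM": arm,
                    "ANALYTE": analyte,
                    "TIME_H": t,
                    "n": n,
                    "p5": q[0],
                    "p50": q[1],
                    "p95": q[2],
                    "frac_bloq": n_bloq / n,
                }
            )
            pending_n = pending_bloq = 0
            pending_t = []
        if pending_t:
            warnings.warn(
                f"trailing bin(s) at t={pending_t} for {arm}/{analyte} had no "
                "quantifiable values; reported as fully censored"
            )
            rows.append(
                {
                    "ARM": arm,
                    "ANALYTE": analyte,
                    "TIME_H": pending_t[-1],
                    "n": pending_n,
                    "p5": np.nan,
                    "p50": np.nan,
                    "p95": np.nan,
                    "frac_bloq": pending_bloq / pending_n,
                }
            )
    return pd.DataFrame(rows)


def vpc(
    dataset: pd.DataFrame,
    pop: PopulationParameters,
    n_sim: int,
    seed: int,
    design: StudyDesign | None = None,
) -> VpcResult:
    """Visual predictive check with a BLOQ-fraction panel.

    Simulates ``n_sim`` replicate studies under the design matching the
    dataset, bins both observed and simulated values at the nominal
    scheduled times, and wraps the observed percentiles with
    simulation-based 90% bands.
    """
    if n_sim < 100:
        raise ValueError("vpc requires n_sim >= 100 for stable bands")
    design = _design_subset(dataset, design or build_monkey_study())
    obs = _binned_stats(dataset)

    child_seeds = (
        np.random.SeedSequence(seed).generate_state(n_sim, dtype=np.uint32)
        & 0x7FFFFFFF
    )
    sims = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate-level bin merges are expected
        for k in range(n_sim):
            rep = simulate_population(design, pop, int(child_seeds[k]))
            s = _binned_stats(rep)
            s["rep"] = k
            sims.append(s)
    sim = pd.concat(sims, ignore_index=True)

    keys = ["ARM", "ANALYTE", "TIME_H"]
    bands = (
        sim.groupby(keys)
        .agg(
            p5_lo=("p5", lambda v: np.nanpercentile(v, 5)),
            p5_hi=("p5", lambda v: np.nanpercentile(v, 95)),
            p50_lo=("p50", lambda v: np.nanpercentile(v, 5)),
            p50_med=("p50", lambda v: np.nanpercentile(v, 50)),
            p50_hi=("p50", lambda v: np.nanpercentile(v, 95)),
            p95_lo=("p95", lambda v: np.nanpercentile(v, 5)),
            p95_hi=("p95", lambda v: np.nanpercentile(v, 95)),
            frac_bloq_sim=("frac_bloq", "mean"),
        )
        .reset_index()
    )
    table = obs.rename(
        columns={
            "p5": "p5_obs",
            "p50": "p50_obs",
            "p95": "p95_obs",
            "frac_bloq": "frac_bloq_obs",
        }
    ).merge(bands, on=keys, how="left")
    return VpcResult(table=table, n_sim=n_sim)


def gof_table(
    fit: FitResult,
    dataset: pd.DataFrame,
    design: StudyDesign | None = None,
    dist: DarDistribution | None = None,
    regimens: dict | None = None,
) -> pd.DataFrame:
    """Observed vs predicted table with residual diagnostics.

    Emits DV, PRED (population prediction, random effects zero), IPRED
    (individual prediction at the MAP random effects), IWRES and a
    FOCE-style conditional weighted residual (CWRES) per record.  BLOQ
    records are flagged and carry no residuals.
    """
    dist = dist or default_dar_distribution()
    if design is None and regimens is None:
        design = build_monkey_study()
    vmodel = build_variant(fit.variant)
    pop = fit.population
    omega = pop.omega_vector()
    eta_by_subj = {
        int(r["SUBJ"]): np.array([r[p] for p in IIV_PARAMETERS])
        for _, r in fit.eta.iterrows()
    }
    subjects = prepare_subjects(dataset, design=design, regimens=regimens)

    frames = []
    for sub in subjects:
        eta = eta_by_subj.get(sub.subj, np.zeros(len(IIV_PARAMETERS)))
        adc_t, mm_t = pop.individual(np.zeros(len(IIV_PARAMETERS)))
        pred = _predict_subject(sub, adc_t, mm_t, dist, vmodel, fit.extra)
        adc_i, mm_i = pop.individual(eta)
        ipred = _predict_subject(sub, adc_i, mm_i, dist, vmodel, fit.extra)

        # gradient of the individual predictions w.r.t. eta (forward diff)
        active = [j for j in range(len(IIV_PARAMETERS)) if omega[j] > 0]
        grads = {code: [] for code in sub.analytes}
        h = 1e-4
        for j in active:
            eta_h = eta.copy()
            eta_h[j] += h
            adc_h, mm_h = pop.individual(eta_h)
            pred_h = _predict_subject(sub, adc_h, mm_h, dist, vmodel, fit.extra)
            for code in sub.analytes:
                grads[code].append((pred_h[code] - ipred[code]) / h)

        order = []
        dv_all, bloq_all, ip_all, pr_all, sg_all, G_rows = [], [], [], [], [], []
        for code, rec in sub.analytes.items():
            sig = pop.sigma[ANALYTE_CODES[code]]
            for k in range(rec["dv"].size):
                order.append((code, k))
                dv_all.append(rec["dv"][k])
                bloq_all.append(rec["bloq"][k])
                ip_all.append(ipred[code][k])
                pr_all.append(pred[code][k])
                sg_all.append(sig)
                G_rows.append([grads[code][a][k] for a in range(len(active))])
        dv_all = np.array(dv_all)
        bloq_all = np.array(bloq_all)
        ip_all = np.array(ip_all)
        pr_all = np.array(pr_all)
        sg_all = np.array(sg_all)
        G = np.array(G_rows) if G_rows else np.zeros((0, len(active)))

        with np.errstate(divide="ignore", invalid="ignore"):
            iwres = np.where(
                (bloq_all == 0) & (ip_all > 0),
                (dv_all - ip_all) / (sg_all * np.maximum(ip_all, 1e-300)),
                np.nan,
            )

        # FOCE-style CWRES: linearise the model in eta at the MAP estimate
        keep = (bloq_all == 0) & (ip_all > 0)
        cwres = np.full(dv_all.size, np.nan)
        if keep.any() and active:
            Gk = G[keep]
            mean_lin = ip_all[keep] - Gk @ eta[active]
            V = Gk @ np.diag(omega[active]) @ Gk.T
            V[np.diag_indices_from(V)] += (sg_all[keep] * ip_all[keep]) ** 2
            L = np.linalg.cholesky(V)
            cwres[keep] = np.linalg.solve(L, dv_all[keep] - mean_lin)

        idx = 0
        rows = []
        for code, rec in sub.analytes.items():
            for k in range(rec["dv"].size):
                rows.append(
                    {
                        "SUBJ": sub.subj,
                        "ANALYTE": code,
                        "TIME_H": sub.grid[rec["time_idx"][k]],
                        "DV": dv_all[idx],
                        "BLOQ": int(bloq_all[idx]),
                        "PRED": pr_all[idx],
                        "IPRED": ip_all[idx],
                        "IWRES": iwres[idx],
                        "CWRES": cwres[idx],
                    }
                )
                idx += 1
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True).sort_values(
        ["SUBJ", "ANALYTE", "TIME_H"], kind="stable"
    ).reset_index(drop=True)


def attribution_report(
    pop: PopulationParameters,
    doses,
    horizon: float = 1008.0,
    n_subjects: int = 100,
    seed: int = 0,
    dist: DarDistribution | None = None,
    body_weight: float | None = None,
) -> pd.DataFrame:
    """Percent of circulating-MMAE input via proteolysis, per dose level.

    For each single IV conjugate dose: the typical-individual value (all
    random effects zero) and a population summary over ``n_subjects``
    simulated individuals, reported as mean and min-max range.
    """
    from .params import DEFAULT_BODY_WEIGHT_KG
    from .simulate import pathway_attribution

    dist = dist or default_dar_distribution()
    bw = body_weight or DEFAULT_BODY_WEIGHT_KG
    times = np.linspace(0.0, horizon, 201)
    rows = []
    for dose_level in np.atleast_1d(doses):
        dose = [model.DoseEvent(0.0, "conjugate", float(dose_level), bw)]
        typical = simulate_individual(dose, pop.adc, pop.mmae, times, dist=dist)
        typ_pct = pathway_attribution(typical).percent_proteolysis
        pcts = []
        for i in range(n_subjects):
            rng = subject_rng(seed, i + 1)
            adc_i, mm_i, _ = sample_individual(pop, rng)
            prof = simulate_individual(dose, adc_i, mm_i, times, dist=dist)
            pcts.append(pathway_attribution(prof).percent_proteolysis)
        pcts = np.array(pcts)
        rows.append(
            {
                "dose_mgkg": float(dose_level),
                "horizon_h": float(horizon),
                "typical_percent": typ_pct,
                "population_mean": float(pcts.mean()),
                "population_min": float(pcts.min()),
                "population_max": float(pcts.max()),
                "n_subjects": int(n_subjects),
                "summary": (
                    f"(mean: {pcts.mean():.0f}%; "
                    f"range: {pcts.min():.0f}–{pcts.max():.0f}%)"
                ),
            }
        )
    return pd.DataFrame(rows)


def dar0_accumulation_report(
    pop: PopulationParameters,
    regimen,
    dist: DarDistribution | None = None,
    points_per_interval: int = 120,
) -> pd.DataFrame:
    """Trough/peak of the unconjugated-antibody (DAR 0) species per interval.

    Under repeated dosing the fully deconjugated antibody can accumulate;
    this report tabulates, for each dose interval, the DAR 0 central
    concentration at its peak and at the trough (just before the next
    dose), plus the trough accumulation ratio relative to interval 1.
    For a single-dose regimen the ratio is 1 by convention.
    """
    dist = dist or default_dar_distribution()
    doses = sorted(regimen, key=lambda d: d.time)
    if not doses:
        raise ValueError("regimen must contain at least one dose")
    interval = (
        np.median(np.diff([d.time for d in doses])) if len(doses) > 1 else 504.0
    )
    t_end = doses[-1].time + interval
    edges = [d.time for d in doses] + [t_end]
    times = np.unique(
        np.concatenate(
            [np.linspace(edges[k], edges[k + 1], points_per_interval) for k in range(len(doses))]
        )
    )
    prof = simulate_individual(doses, pop.adc, pop.mmae, times, dist=dist)
    dar0 = prof.dar_species[:, 0]  # nM antibody

    rows = []
    trough1 = None
    for k in range(len(doses)):
        m = (times > edges[k]) & (times <= edges[k + 1])
        peak = float(dar0[m].max()) if m.any() else np.nan
        trough = float(dar0[m][-1]) if m.any() else np.nan
        if k == 0:
            trough1 = trough
        ratio = 1.0 if k == 0 else (trough / trough1 if trough1 and trough1 > 0 else np.nan)
        rows.append(
            {
                "interval": k + 1,
                "t_start": edges[k],
                "t_end": edges[k + 1],
                "dar0_peak_nM": peak,
                "dar0_trough_nM": trough,
                "trough_accumulation_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
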