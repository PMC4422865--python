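"""Study designs and dataset I/O.

Reconstructs the cynomolgus-monkey study layout used throughout the
package as a first-class object, and reads/writes the tidy long-format
concentration dataset (plus a NONMEM-style export).  Together with
:func:`generate_dataset` this makes every other module testable without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DoseEvent
from .params import DEFAULT_BODY_WEIGHT_KG, DarDistribution, PopulationParameters
from .simulate import ANALYTE_CODES, ANALYTE_UNITS, DATASET_COLUMNS, DEFAULT_LLOQ

__all__ = [
    "Arm",
    "StudyDesign",
    "build_monkey_study",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
    "to_nonmem",
    "from_nonmem",
    "Q3W_HOURS",
]

#: Every-three-weeks dosing interval in hours.
Q3W_HOURS = 504.0

#: 5 minutes expressed exactly in hours.
FIVE_MIN = 1.0 / 12.0


@dataclass
class Arm:
    """One treatment arm: a regimen plus per-analyte sampling schedules."""

    name: str
    compound: str  # "conjugate" | "mmae"
    dose_level: float  # mg/kg
    n_subjects: int
    dose_times: list
    schedule: dict  # analyte code -> sorted sampling times (h)
    body_weight: float = DEFAULT_BODY_WEIGHT_KG

    def __post_init__(self) -> None:
        if self.compound not in ("conjugate", "mmae"):
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for code, times in self.schedule.items():
            if code not in ANALYTE_CODES:
                raise ValueError(f"unknown analyte code {code!r}")
            t = np.asarray(times, dtype=float)
            if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
                raise ValueError(f"schedule for {code} must be sorted, non-negative")

    def regimen(self) -> list:
        return [
            DoseEvent(
                time=float(t),
                compound=self.compound,
                dose_level=self.dose_level,
                body_weight=self.body_weight,
            )
            for t in self.dose_times
        ]

    def simulation_grid(self) -> np.ndarray:
        """Union of all analyte schedules."""
        return np.unique(np.concatenate([np.asarray(t, float) for t in self.schedule.values()]))

    def n_scheduled_records(self) -> int:
        return self.n_subjects * sum(len(t) for t in self.schedule.values())


@dataclass
class StudyDesign:
    """A collection of arms plus dosing-solution and assay metadata."""

    arms: list
    dar_distribution: DarDistribution | None = None
    lloq: dict = field(default_factory=lambda: dict(DEFAULT_LLOQ))

    @property
    def n_subjects(self) -> int:
        return sum(a.n_subjects for a in self.arms)

    def n_scheduled_records(self) -> int:
        return sum(a.n_scheduled_records() for a in self.arms)

    def arm(self, name: str) -> Arm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"no arm named {name!r}")


def build_monkey_study(body_weight: float = DEFAULT_BODY_WEIGHT_KG) -> StudyDesign:
    """The three-part cynomolgus-monkey PK study design.

    * single IV conjugate doses 0.3, 1 and 3 mg/kg, 4 monkeys each, all
      three analytes sampled pre-dose, at 5 min and out to 1008 h;
    * 3 or 5 mg/kg conjugate every three weeks for 4 doses, 10 monkeys
      each, total antibody and unconjugated MMAE sampled richly after the
      first and fourth doses and pre-dose/0.25 h after doses 2-3;
    * single IV unconjugated MMAE at 0.03 or 0.063 mg/kg, 10 monkeys each.
    """
    single_times = [0.0, FIVE_MIN, 4, 12, 24, 72, 168, 336, 504, 672, 840, 1008]
    arms = [
        Arm(
            name=f"adc-single-{dose:g}",
            compound="conjugate",
            dose_level=dose,
            n_subjects=4,
            dose_times=[0.0],
            schedule={
                "TAB": list(single_times),
                "ACMMAE": list(single_times),
                "MMAE": list(single_times),
            },
            body_weight=body_weight,
        )
        for dose in (0.3, 1.0, 3.0)
    ]

    offsets = [0.0, 0.25, 6, 24, 72, 168, 336, 504]
    q3w_doses = [0.0, Q3W_HOURS, 2 * Q3W_HOURS, 3 * Q3W_HOURS]
    q3w_times = sorted(
        set(
            [o for o in offsets]  # after dose 1
            + [3 * Q3W_HOURS + o for o in offsets]  # after dose 4
            + [Q3W_HOURS, Q3W_HOURS + 0.25]  # pre-dose / 0.25 h, dose 2
            + [2 * Q3W_HOURS, 2 * Q3W_HOURS + 0.25]  # pre-dose / 0.25 h, dose 3
        )
    )
    arms += [
        Arm(
            name=f"adc-q3w-{dose:g}",
            compound="conjugate",
            dose_level=dose,
            n_subjects=10,
            dose_times=list(q3w_doses),
            schedule={"TAB": list(q3w_times), "MMAE": list(q3w_times)},
            body_weight=body_weight,
        )
        for dose in (3.0, 5.0)
    ]

    mmae_times = [0.0, 2 / 60, 10 / 60, 30 / 60, 1, 3, 10, 24, 48, 168, 240, 504]
    arms += [
        Arm(
            name=f"mmae-{dose:g}",
            compound="mmae",
            dose_level=dose,
            n_subjects=10,
            dose_times=[0.0],
            schedule={"MMAE": list(mmae_times)},
            body_weight=body_weight,
        )
        for dose in (0.03, 0.063)
    ]
    return StudyDesign(arms=arms)


def generate_dataset(
    design: StudyDesign, pop: PopulationParameters, seed: int
) -> pd.DataFrame:
    """Seeded synthetic dataset for ``design`` (delegates to simulation)."""
    from .simulate import simulate_population

    return simulate_population(design, pop, seed)


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write the long-format dataset to CSV (BLOQ values stay withheld)."""
    dataset.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format concentration dataset."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    bad = sorted(set(df["ANALYTE"]) - set(ANALYTE_CODES))
    if bad:
        raise ValueError(f"unknown ANALYTE code(s): {bad}; allowed: {sorted(ANALYTE_CODES)}")
    bad_bloq = sorted(set(df["BLOQ"]) - {0, 1})
    if bad_bloq:
        raise ValueError(f"BLOQ flags must be 0 or 1, found: {bad_bloq}")
    for (subj, analyte), grp in df.groupby(["SUBJ", "ANALYTE"], sort=False):
        t = grp["TIME_H"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(
                f"times for subject {subj}, analyte {analyte} are not sorted"
            )
    if ((~df["DV"].isna()) & (df["DV"] <= 0)).any():
        raise ValueError("non-censored DV values must be positive")
    df = df[DATASET_COLUMNS].copy()
    df["BLOQ"] = df["BLOQ"].astype(int)
    df["SUBJ"] = df["SUBJ"].astype(int)
    return df


_CMT_BY_ANALYTE = {"TAB": 1, "ACMMAE": 2, "MMAE": 3}
_DOSE_CMT = {"conjugate": 1, "mmae": 3}


def to_nonmem(dataset: pd.DataFrame, design: StudyDesign, path=None) -> pd.DataFrame:
    """NONMEM-style export: dose rows (EVID=1) interleaved with observations.

    Columns: ID, TIME, AMT, DV, CMT, EVID, MDV, LLOQ, BLQ, BW, DOSE_MGKG,
    CMPD.  BLOQ records carry DV = LLOQ with BLQ = 1 (M3 convention).
    """
    arm_by_name = {a.name: a for a in design.arms}
    rows = []
    for subj, grp in dataset.groupby("SUBJ", sort=True):
        arm = arm_by_name[grp["ARM"].iloc[0]]
        bw = float(grp["BW_KG"].iloc[0])
        for dose in arm.regimen():
            rows.append(
                dict(
                    ID=subj, TIME=dose.time, AMT=dose.amount,
                    DV=np.nan, CMT=_DOSE_CMT[dose.compound], EVID=1, MDV=1,
                    LLOQ=np.nan, BLQ=0, BW=bw,
                    DOSE_MGKG=dose.dose_level, CMPD=dose.compound,
                )
            )
        for _, r in grp.iterrows():
            bloq = int(r["BLOQ"])
            rows.append(
                dict(
                    ID=subj, TIME=r["TIME_H"],
                    AMT=0.0, DV=r["LLOQ"] if bloq else r["DV"],
                    CMT=_CMT_BY_ANALYTE[r["ANALYTE"]], EVID=0, MDV=0,
                    LLOQ=r["LLOQ"], BLQ=bloq, BW=bw,
                    DOSE_MGKG=r["DOSE_MGKG"], CMPD=r["CMPD"],
                )
            )
    out = pd.DataFrame(rows).sort_values(
        ["ID", "TIME", "EVID"], kind="stable", ascending=[True, True, False]
    ).reset_index(drop=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def nonmem_regimens(nm: pd.DataFrame) -> dict:
    """Extract per-subject dose events from a NONMEM-style table."""
    out = {}
    for _, r in nm[nm["EVID"] == 1].iterrows():
        out.setdefault(int(r["ID"]), []).append(
            DoseEvent(
                time=float(r["TIME"]),
                compound=str(r["CMPD"]),
                dose_level=float(r["DOSE_MGKG"]),
                body_weight=float(r["BW"]),
            )
        )
    return out


def from_nonmem(nm: pd.DataFrame | str, arm_name: str = "imported") -> pd.DataFrame:
    """Rebuild the long-format observation table from a NONMEM-style table.

    Dose rows are dropped (regimens live in the design); the result has the
    standard columns and reproduces the original likelihood inputs.
    """
    if not isinstance(nm, pd.DataFrame):
        nm = pd.read_csv(nm)
    obs = nm[nm["EVID"] == 0].copy()
    code_by_cmt = {v: k for k, v in _CMT_BY_ANALYTE.items()}
    out = pd.DataFrame(
        {
            "SUBJ": obs["ID"].astype(int),
            "ARM": arm_name,
            "TIME_H": obs["TIME"].astype(float),
            "ANALYTE": obs["CMT"].map(code_by_cmt),
            "DV": np.where(obs["BLQ"] == 1, np.nan, obs["DV"]),
            "BLOQ": obs["BLQ"].astype(int),
            "LLOQ": obs["LLOQ"].astype(float),
            "DOSE_MGKG": obs["DOSE_MGKG"],
            "CMPD": obs["CMPD"],
            "BW_KG": obs["BW"].astype(float),
            "OCC": 1,
        }
    )
    out["UNIT"] = out["ANALYTE"].map(ANALYTE_UNITS)
    return out[DATASET_COLUMNS].reset_index(drop=True)
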