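"""Relative gene copy number from qPCR quantification cycles.

Copy number of a multigene target is estimated relative to a single-copy
reference gene (here superoxide dismutase I) from the difference of mean
quantification cycles: ratio = efficiency^(Cq_ref - Cq_target), with the
amplification efficiency defaulting to ideal doubling (2.0 per cycle).
A Welch two-sample t-test compares ratio sets across primer sets or
populations; the Welch form (Satterthwaite fractional degrees of freedom)
is the default because replicate variances are rarely equal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PRIMER_SETS = ("woodrat_specific", "rodent_conserved", "reference")


@dataclass(frozen=True)
class QpcrWellSet:
    """Replicate Cq values of one (sample, primer set) combination."""

    sample_id: str
    population: str
    primer_set: str
    cq: tuple[float, ...]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.primer_set not in PRIMER_SETS:
            raise ValueError(f"unknown primer set {self.primer_set!r}")
        if len(self.cq) < 2:
            raise ValueError("need >=2 replicate Cq values")
        if any(c <= 0 for c in self.cq):
            raise ValueError("Cq values must be positive")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq))

    @property
    def sd_cq(self) -> float:
        return float(np.std(self.cq, ddof=1))


class CopyRatio(NamedTuple):
    ratio: float
    sd: float  # propagated from replicate scatter of both well sets


def copy_ratio(target: QpcrWellSet, reference: QpcrWellSet) -> CopyRatio:
    """Relative copy number of ``target`` against the single-copy reference.

    ratio = E_ref^mean(Cq_ref) / E_target^mean(Cq_target), which reduces to
    E^(Cq_ref - Cq_target) for a shared efficiency E.  Replicate standard
    deviations propagate through the log-ratio; a replicate SD above 0.5
    cycles triggers a warning.
    """
    if target.sample_id != reference.sample_id:
        raise ValueError(
            f"sample mismatch: {target.sample_id!r} vs {reference.sample_id!r}"
        )
    if reference.primer_set != "reference":
        raise ValueError("reference well set must use the reference primer set")
    for ws in (target, reference):
        if ws.sd_cq > 0.5:
            warnings.warn(
                f"{ws.sample_id}/{ws.primer_set}: replicate SD "
                f"{ws.sd_cq:.2f} cycles exceeds 0.5"
            )
    ratio = reference.efficiency ** reference.mean_cq / (
        target.efficiency ** target.mean_cq
    )
    var_log = (
        math.log(target.efficiency) ** 2 * target.sd_cq**2 / len(target.cq)
        + math.log(reference.efficiency) ** 2
        * reference.sd_cq**2
        / len(reference.cq)
    )
    return CopyRatio(ratio=float(ratio), sd=float(ratio * math.sqrt(var_log)))


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t(group1: Sequence[float], group2: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (Satterthwaite df), two-sided."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if g1.mean() == g2.mean():
            warnings.warn("zero variance and equal means: t undefined")
            return WelchResult(float("nan"), float("nan"), float("nan"))
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def read_qpcr_tsv(path: str | Path, efficiency: float = 2.0) -> list[QpcrWellSet]:
    """Read well sets from a TSV with columns
    sample, population, primer_set, cq (one row per replicate)."""
    df = pd.read_csv(Path(path), sep="\t")
    required = {"sample", "population", "primer_set", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    wells = []
    for (sample, pop, primer), sub in df.groupby(
        ["sample", "population", "primer_set"], sort=True
    ):
        wells.append(
            QpcrWellSet(
                sample_id=str(sample),
                population=str(pop),
                primer_set=str(primer),
                cq=tuple(float(c) for c in sub["cq"]),
                efficiency=efficiency,
            )
        )
    return wells


def copy_ratio_table(wells: Sequence[QpcrWellSet]) -> pd.DataFrame:
    """Per-sample copy ratios of every target primer set vs the reference."""
    by_sample: dict[str, dict[str, QpcrWellSet]] = {}
    for w in wells:
        by_sample.setdefault(w.sample_id, {})[w.primer_set] = w
    rows = []
    for sample, sets in sorted(by_sample.items()):
        if "reference" not in sets:
            raise ValueError(f"sample {sample!r} lacks a reference well set")
        ref = sets["reference"]
        for primer, target in sorted(sets.items()):
            if primer == "reference":
                continue
            r = copy_ratio(target, ref)
            rows.append(
                {
                    "sample": sample,
                    "population": target.population,
                    "primer_set": primer,
                    "ratio": r.ratio,
                    "sd": r.sd,
                }
            )
    return pd.DataFrame(rows)
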