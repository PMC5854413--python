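"""Between-method agreement statistics for paired SUR measurements.

Implements the comparison toolkit used to judge an automatic
quantification method against manual ROI analysis:

* percent error            |m - a| / m * 100
* per-subject variability  |m - a| / ((m + a) / 2), summarized mean +/- SD
* one-way random-effects ICC(1,1)  (MSBS - MSWS) / (MSBS + (k-1) MSWS),
  k = 2 (manual and automatic), returned unclamped — negative values mean
  the between-method disagreement exceeds the between-subject spread
* Pearson correlation
* Bland-Altman mean difference (manual - automatic) with 1.96 SD limits
* pooled-variance two-sample Student t-test (Welch behind a flag)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

KNOWN_METHOD_SYNONYMS = ("manual", "mbt", "hbt", "hmpao")


def percent_error(sur_manual: float, sur_automatic: float) -> float:
    """|manual - automatic| / manual * 100.

    The denominator is the signed manual value as conventionally printed;
    with a positive manual SUR this equals the fully absolute form.
    """
    if sur_manual == 0:
        raise ValueError("percent error undefined for sur_manual == 0")
    return abs(sur_manual - sur_automatic) / sur_manual * 100.0


def variability(sur_manual: float, sur_automatic: float) -> float:
    """|manual - automatic| relative to the pair mean."""
    mean_pair = (sur_manual + sur_automatic) / 2.0
    if mean_pair == 0:
        raise ValueError("variability undefined when the pair mean is 0")
    return abs(sur_manual - sur_automatic) / mean_pair


@dataclass
class ICCComponents:
    """One-way ANOVA components behind the ICC."""

    msbs: float     # mean square between subjects
    msws: float     # mean square within subjects
    k: int          # measurements per subject (2: manual + automatic)
    n: int          # subjects

    @property
    def icc(self) -> float:
        denom = self.msbs + (self.k - 1) * self.msws
        if denom == 0:
            return 1.0 if self.msws == 0 else 0.0
        return (self.msbs - self.msws) / denom


def icc_oneway(pairs: Sequence[tuple[float, float]]) -> tuple[float, ICCComponents]:
    """One-way random-effects ICC(1,1) for paired measurements.

    Values are returned unclamped: a negative ICC is meaningful (more
    within-subject than between-subject variance) and is reported as-is.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("pairs must be an (n, k>=2) array-like")
    n, k = arr.shape
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    subj_means = arr.mean(axis=1)
    grand = arr.mean()
    msbs = k * float(np.sum((subj_means - grand) ** 2)) / (n - 1)
    msws = float(np.sum((arr - subj_means[:, None]) ** 2)) / (n * (k - 1))
    comp = ICCComponents(msbs=msbs, msws=msws, k=k, n=n)
    return comp.icc, comp


def pearson(pairs: Sequence[tuple[float, float]]) -> float:
    """Sample Pearson correlation of the paired columns."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("pearson requires at least 2 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for a zero-variance column")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    diffs: np.ndarray
    means: np.ndarray


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    direction: str = "manual_minus_automatic",
) -> BlandAltman:
    """Bland-Altman agreement: per-pair differences vs means.

    ``direction`` fixes the sign of the differences; the default
    (manual - automatic) makes a systematically higher automatic method
    show a negative mean difference. Limits of agreement are
    mean +/- 1.96 SD (sample SD, n-1).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("bland_altman requires at least 2 pairs")
    diffs = arr[:, 0] - arr[:, 1]
    if direction == "automatic_minus_manual":
        diffs = -diffs
    elif direction != "manual_minus_automatic":
        raise ValueError(f"unknown direction {direction!r}")
    means = arr.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        sd_diff=sd,
        diffs=diffs,
        means=means,
    )


def ttest_two_sample(
    a: Iterable[float], b: Iterable[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sample Student t-test (pooled variance; Welch behind a flag)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


@dataclass
class PairedSURTable:
    """Per-subject SUR values: one manual column, >=1 automatic columns."""

    data: pd.DataFrame   # columns: subject_id, manual, <method labels...>

    def __post_init__(self) -> None:
        cols = {c.lower(): c for c in self.data.columns}
        if "subject_id" not in cols:
            self.data = self.data.copy()
            self.data.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(len(self.data))])
        else:
            self.data = self.data.rename(columns={cols["subject_id"]: "subject_id"})
        if self.data["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")
        lowered = {c: c.lower() for c in self.data.columns if c != "subject_id"}
        self.data = self.data.rename(columns=lowered)
        if "manual" not in self.data.columns:
            raise ValueError("table needs a 'manual' column")

    @property
    def methods(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("subject_id", "manual")]

    def pairs(self, method: str) -> np.ndarray:
        method = method.lower()
        if method not in self.data.columns:
            raise KeyError(f"method column {method!r} not in table (have {self.methods})")
        sub = self.data[["manual", method]].astype(float)
        if sub.isna().any().any():
            raise ValueError(f"missing values in manual/{method} pair")
        return sub.to_numpy()

    @classmethod
    def from_file(
        cls,
        path: Union[str, Path],
        column_mapping: dict[str, str] | None = None,
    ) -> "PairedSURTable":
        """Read a paired-SUR table from CSV or XLSX.

        Header matching is case-insensitive; ``column_mapping`` (original
        name -> manual/mbt/hbt/...) overrides the automatic matching.
        """
        path = Path(path)
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
        if column_mapping:
            df = df.rename(columns=column_mapping)
        return cls(df)


@dataclass
class AgreementReport:
    """Everything needed to compare one automatic method against manual."""

    method: str
    n: int
    pearson_r: float
    variability_mean: float
    variability_sd: float
    mean_diff: float
    loa_low: float
    loa_high: float
    icc: float
    icc_components: ICCComponents
    excluded_subjects: list[str] = field(default_factory=list)
    bland_altman: BlandAltman | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "variability_mean": self.variability_mean,
            "variability_sd": self.variability_sd,
            "mean_diff": self.mean_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "icc": self.icc,
            "msbs": self.icc_components.msbs,
            "msws": self.icc_components.msws,
            "excluded_subjects": self.excluded_subjects,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def plot_agreement(table: PairedSURTable, method: str, outdir: Union[str, Path]) -> list[Path]:
    """Write Bland-Altman and scatter PNGs for one method (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arr = table.pairs(method)
    ba = bland_altman(arr)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18)
    ax.axhline(ba.mean_diff, color="red", label=f"bias {ba.mean_diff:.2f}")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="gray", linestyle="--")
    ax.set_xlabel("pair mean SUR")
    ax.set_ylabel("manual − automatic")
    ax.set_title(f"Bland–Altman: manual vs {method}")
    ax.legend()
    p = outdir / f"bland_altman_{method}.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(arr[:, 0], arr[:, 1], s=18)
    lims = [min(arr.min(), 0), arr.max() * 1.05]
    ax.plot(lims, lims, color="gray", linestyle=":")
    ax.set_xlabel("manual SUR")
    ax.set_ylabel(f"{method} SUR")
    ax.set_title(f"r = {pearson(arr):.2f}")
    p = outdir / f"scatter_{method}.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths


def agreement_report(table: PairedSURTable, method: str) -> AgreementReport:
    """Full agreement panel of one automatic method against manual.

    Pearson correlation, per-subject variability summarized as
    mean +/- sample SD (subjects with a zero pair mean are excluded and
    listed), Bland-Altman (manual - automatic) and one-way ICC. Invariant
    to row order.
    """
    arr = table.pairs(method)
    ids = table.data["subject_id"].tolist()
    var_values = []
    excluded = []
    for sid, (m, a) in zip(ids, arr):
        try:
            var_values.append(variability(m, a))
        except ValueError:
            excluded.append(sid)
    if not var_values:
        raise ValueError("no subject with a nonzero pair mean; variability undefined")
    var_arr = np.asarray(var_values)
    ba = bland_altman(arr)
    icc, comp = icc_oneway(arr)
    return AgreementReport(
        method=method,
        n=len(arr),
        pearson_r=pearson(arr),
        variability_mean=float(var_arr.mean()),
        variability_sd=float(var_arr.std(ddof=1)) if len(var_arr) > 1 else 0.0,
        mean_diff=ba.mean_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        icc=icc,
        icc_components=comp,
        excluded_subjects=excluded,
        bland_altman=ba,
    )
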