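"""Dosage-imbalance analysis: expression ratios, binned distributions, landmarks.

The central diagnostic is the per-feature aneuploid/euploid expression ratio,
computed on CPM as mean(case replicates) / mean(control replicates), and its
0.1-binned percentage-frequency histogram, drawn separately for cis features
(on the dose-varied chromosome arm) and trans features (rest of the genome).

Analytic landmarks anchor the interpretation: a ratio of 1.0 is dosage
compensation (cis) or no response (trans); case_dose/control_dose (1.5 in a
trisomy) is a proportional gene-dosage effect; control_dose/case_dose (2/3 in
a trisomy) is the inverse dosage effect.  Each feature is assigned to its
nearest landmark on the log scale, within a multiplicative tolerance window,
and distributions of different transcript classes are compared with two-sample
Kolmogorov-Smirnov tests on the unbinned ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix, UNIT_CPM, UNIT_TE_FRACTION

logger = logging.getLogger(__name__)

CIS = "cis"
TRANS = "trans"

#: classification labels, by location
CIS_LABELS = {"one": "compensated", "direct": "dosage_effect", "inverse": "inverse"}
TRANS_LABELS = {"one": "unchanged", "direct": "direct", "inverse": "inverse"}


@dataclass(frozen=True)
class KaryotypeSpec:
    """Per-chromosome-arm copy numbers of one genotype.

    ``doses`` maps arm name to copy number, e.g. trisomy 2L female:
    ``{"X": 2, "2L": 3, "2R": 2, ...}``.  ``control_genotype`` names the
    euploid reference this genotype is compared against.
    """

    genotype: str
    doses: dict[str, int]
    control_genotype: str = ""

    def __post_init__(self) -> None:
        for arm, d in self.doses.items():
            if not (isinstance(d, int) and d > 0):
                raise ValueError(f"{self.genotype}: dose for {arm} must be a positive integer")


def varied_arms(case: KaryotypeSpec, control: KaryotypeSpec) -> list[str]:
    """Arms whose copy number differs between case and control."""
    arms = set(case.doses) | set(control.doses)
    missing = [a for a in arms if a not in case.doses or a not in control.doses]
    if missing:
        raise ValueError(f"arms missing from one karyotype: {sorted(missing)}")
    return sorted(a for a in arms if case.doses[a] != control.doses[a])


@dataclass(frozen=True)
class DosageLandmarks:
    """Analytic ratio landmarks for one varied arm (trisomy: 1.0, 1.5, 2/3)."""

    arm: str
    compensation: float
    dosage_effect: float
    inverse: float

    def as_dict(self) -> dict[str, float]:
        return {
            "compensation": self.compensation,
            "dosage_effect": self.dosage_effect,
            "inverse": self.inverse,
        }


def dosage_landmarks(
    case: KaryotypeSpec, control: KaryotypeSpec
) -> dict[str, DosageLandmarks]:
    """Landmark ratios per varied arm; errors if no arm is varied."""
    arms = varied_arms(case, control)
    if not arms:
        raise ValueError(
            f"{case.genotype} vs {control.genotype}: not aneuploid (no varied arm)"
        )
    out = {}
    for arm in arms:
        cd, xd = control.doses[arm], case.doses[arm]
        out[arm] = DosageLandmarks(arm, 1.0, xd / cd, cd / xd)
    return out


def assign_cis_trans(
    chroms: pd.Series | list[str], case: KaryotypeSpec, control: KaryotypeSpec
) -> pd.Series:
    """cis iff the feature's arm is dose-varied in this comparison."""
    varied = set(varied_arms(case, control))
    chroms = pd.Series(chroms)
    unknown = sorted(set(chroms) - set(case.doses))
    if unknown:
        raise ValueError(f"chromosome arms absent from karyotype: {unknown}")
    return chroms.map(lambda c: CIS if c in varied else TRANS)


@dataclass
class RatioTable:
    """Per-feature case/control expression ratios with location labels.

    ``table`` columns: feature_id, biotype, chrom, location, ratio (and
    optionally klass after classification).  ``n_dropped`` counts features
    excluded because their control mean was zero.
    """

    table: pd.DataFrame
    comparison: str = ""
    n_dropped: int = 0

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()


def expression_ratio(
    expr: CountMatrix,
    case_samples: list[str],
    control_samples: list[str],
    annotation: pd.DataFrame | None = None,
    comparison: str = "",
) -> RatioTable:
    """Per-feature ratio of mean case expression over mean control expression.

    ``expr`` must be normalized (CPM, or TE family fractions).  Features whose
    control mean is zero are dropped and counted in ``n_dropped``.  If
    ``annotation`` (feature_id, biotype, chrom[, location]) is given, it is
    joined onto the result.
    """
    if expr.unit not in (UNIT_CPM, UNIT_TE_FRACTION):
        raise ValueError(f"expression_ratio expects normalized values, got {expr.unit}")
    if not case_samples or not control_samples:
        raise ValueError("expression_ratio: empty sample group")
    case_mean = expr.values[case_samples].mean(axis=1)
    ctrl_mean = expr.values[control_samples].mean(axis=1)
    ok = ctrl_mean > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("expression_ratio: dropped %d features with zero control mean", n_dropped)
    tab = pd.DataFrame(
        {"feature_id": expr.values.index[ok], "ratio": (case_mean[ok] / ctrl_mean[ok]).to_numpy()}
    )
    if annotation is not None:
        tab = tab.merge(annotation, on="feature_id", how="left")
        cols = ["feature_id"] + [c for c in ("biotype", "chrom", "location") if c in tab]
        tab = tab[cols + ["ratio"]]
    return RatioTable(tab, comparison=comparison, n_dropped=n_dropped)


@dataclass
class RatioDistribution:
    """0.1-binned percentage-frequency histogram of expression ratios.

    Bins are right-open [k*w, (k+1)*w) with an overflow bin pooling ratios
    >= cap; ``percent`` sums to 100.  Raw ratios are retained for K-S testing.
    """

    group: str
    bin_edges: np.ndarray
    percent: np.ndarray
    n: int
    raw_ratios: np.ndarray = field(repr=False, default=None)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "percent": self.percent,
                "group": self.group,
            }
        )


def build_ratio_distribution(
    ratios, group: str = "", bin_width: float = 0.1, cap: float = 3.0
) -> RatioDistribution:
    """Bin positive ratios into right-open width-0.1 bins plus an overflow bin."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("build_ratio_distribution: empty input")
    if (r <= 0).any():
        raise ValueError("build_ratio_distribution: ratios must be positive")
    n_bins = int(round(cap / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum(np.floor(r / bin_width).astype(int), n_bins)  # n_bins = overflow
    counts = np.bincount(idx, minlength=n_bins + 1)
    percent = 100.0 * counts / r.size
    edges = np.append(edges, np.inf)  # overflow bin [cap, inf)
    return RatioDistribution(group, edges, percent, int(r.size), raw_ratios=r)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def ks_compare(ratios_a, ratios_b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test on unbinned ratios (asymptotic p)."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_compare: both samples need size >= 2")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def classify_dosage_response(
    ratio: float,
    location: str,
    landmarks: DosageLandmarks,
    rel_tol: float = 0.10,
) -> str:
    """Assign a ratio to its nearest landmark on the log scale.

    Returns (cis) compensated / dosage_effect / inverse / other, or (trans)
    unchanged / direct / inverse / other.  "other" when the log distance to
    every landmark exceeds log(1 + rel_tol).
    """
    if ratio <= 0:
        raise ValueError("classify_dosage_response: ratio must be positive")
    names = CIS_LABELS if location == CIS else TRANS_LABELS
    marks = {
        "one": landmarks.compensation,
        "direct": landmarks.dosage_effect,
        "inverse": landmarks.inverse,
    }
    logr = math.log(ratio)
    dists = {k: abs(logr - math.log(v)) for k, v in marks.items()}
    best = min(sorted(dists), key=dists.get)
    if dists[best] > math.log1p(rel_tol):
        return "other"
    return names[best]


def classify_ratio_table(
    rt: RatioTable, landmarks: DosageLandmarks, rel_tol: float = 0.10
) -> pd.DataFrame:
    """Vectorized nearest-landmark classification of a whole RatioTable."""
    tab = rt.table.copy()
    tab["klass"] = [
        classify_dosage_response(r, loc, landmarks, rel_tol)
        for r, loc in zip(tab["ratio"], tab.get("location", pd.Series([TRANS] * len(tab))))
    ]
    return tab


def find_distribution_peaks(dist: RatioDistribution, k: int = 3) -> pd.DataFrame:
    """Local maxima of the binned percentages, ranked by height.

    Ties break toward the smaller ratio.  A flat histogram has no distinct
    peak; the first bin is returned flagged ``distinct=False``.
    """
    p = dist.percent
    centers = np.where(np.isfinite(dist.bin_centers), dist.bin_centers, dist.bin_edges[-2])
    peaks = []
    for i in range(len(p)):
        left = p[i - 1] if i > 0 else -np.inf
        right = p[i + 1] if i < len(p) - 1 else -np.inf
        if p[i] > left and p[i] > right and p[i] > 0:
            peaks.append(i)
    if not peaks:
        return pd.DataFrame(
            {"bin_center": [centers[0]], "percent": [p[0]], "distinct": [False]}
        )
    peaks.sort(key=lambda i: (-p[i], centers[i]))
    sel = peaks[:k]
    return pd.DataFrame(
        {
            "bin_center": [centers[i] for i in sel],
            "percent": [p[i] for i in sel],
            "distinct": [True] * len(sel),
        }
    )
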