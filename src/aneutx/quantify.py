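"""Count loading, CPM normalization, low-expression filtering and TE family sums.

The pipeline order is fixed: filter on *raw* counts (mean across samples
strictly greater than ``min_mean``), then normalize to counts-per-million.
TE insertions are summed into family-level counts before any normalization;
TE family distributions use within-TE fractional shares rather than CPM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNIT_RAW = "raw_counts"
UNIT_CPM = "cpm"
UNIT_TE_FRACTION = "te_fraction"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    sex: str
    replicate: int


@dataclass
class CountMatrix:
    """Feature-by-sample expression values with metadata and an explicit unit.

    ``values`` is a pandas DataFrame indexed by feature_id with sample_id
    columns; ``samples`` holds one SampleMeta per column, in column order.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    unit: str = UNIT_RAW

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("CountMatrix: negative values")
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("CountMatrix: sample metadata does not match columns")
        if len({(s.genotype, s.replicate) for s in self.samples}) != len(self.samples):
            raise ValueError("CountMatrix: duplicate (genotype, replicate)")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_for(self, genotype: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.genotype == genotype]

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[feature_ids], list(self.samples), self.unit)


@dataclass
class FamilyCounts:
    """Per-TE-family count sums with the number of insertions per family."""

    values: pd.DataFrame
    samples: list[SampleMeta]
    n_insertions: dict[str, int] = field(default_factory=dict)

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.index)


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column feature_id) and a metadata TSV."""
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype", "sex", "replicate"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id").loc[list(values.columns)].reset_index()
    samples = [
        SampleMeta(r.sample_id, r.genotype, r.sex, int(r.replicate))
        for r in meta.itertuples()
    ]
    return CountMatrix(values, samples, UNIT_RAW)


def cpm_normalize(m: CountMatrix) -> CountMatrix:
    """Counts per million: value / column_sum * 1e6, per sample."""
    if m.unit != UNIT_RAW:
        raise ValueError(f"cpm_normalize expects raw counts, got unit={m.unit}")
    sums = m.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return CountMatrix(m.values / sums * 1e6, list(m.samples), UNIT_CPM)


def filter_low_expression(m: CountMatrix, min_mean: float = 5.0) -> CountMatrix:
    """Keep features whose mean raw count across all samples is > min_mean (strict)."""
    if m.unit != UNIT_RAW:
        raise ValueError("filter_low_expression runs on raw counts, before CPM")
    keep = m.values.mean(axis=1) > min_mean
    logger.info(
        "filter_low_expression: kept %d / %d features (mean > %g)",
        int(keep.sum()), len(keep), min_mean,
    )
    return CountMatrix(m.values.loc[keep], list(m.samples), UNIT_RAW)


def aggregate_te_families(m: CountMatrix, family_map: dict[str, str]) -> FamilyCounts:
    """Sum TE insertion counts into family totals (families sorted lexicographically)."""
    missing = [f for f in m.feature_ids if f not in family_map]
    if missing:
        raise ValueError(f"insertions missing from family map: {missing[:10]}")
    fam = pd.Series({f: family_map[f] for f in m.feature_ids}, name="family")
    grouped = m.values.groupby(fam).sum().sort_index()
    n_ins = fam.value_counts().sort_index().to_dict()
    return FamilyCounts(grouped, list(m.samples), n_ins)


def te_fraction_normalize(fc: FamilyCounts) -> CountMatrix:
    """Normalize each family by the per-sample total TE expression (shares sum to 1)."""
    sums = fc.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero total TE expression in sample(s): {list(zero.index)}")
    return CountMatrix(fc.values / sums, list(fc.samples), UNIT_TE_FRACTION)


def top_family_shares(shares: CountMatrix, k: int = 20) -> pd.DataFrame:
    """Per-sample top-k family shares (pie-chart style summary).

    Returns a long DataFrame (sample_id, family, share, rank).
    """
    if shares.unit != UNIT_TE_FRACTION:
        raise ValueError("top_family_shares expects te_fraction unit")
    rows = []
    for col in shares.values.columns:
        top = shares.values[col].sort_values(ascending=False, kind="stable").head(k)
        for rank, (family, share) in enumerate(top.items(), start=1):
            rows.append((col, family, float(share), rank))
    return pd.DataFrame(rows, columns=["sample_id", "family", "share", "rank"])


def write_counts(m: CountMatrix, path: str | Path) -> None:
    """Write values as TSV with a sidecar JSON recording the unit."""
    path = Path(path)
    m.values.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"unit": m.unit, "n_features": len(m.values)}) + "\n")
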