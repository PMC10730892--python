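"""Annotation handling and positional classification of lncRNAs and TE insertions.

Transcripts are read from an Ensembl-dialect GTF; TE insertions come either from
GTF rows or from a simple TSV plus a family map.  Each noncoding feature is then
placed into one of four positional categories relative to the protein-coding
annotation: intergenic (called *lincRNA* for lncRNAs), *intronic*, *sense* and
*antisense*.  The decision rule, applied per feature:

1. no base overlap with any protein-coding transcript span -> lincRNA/intergenic;
2. any span overlap with a coding transcript on the opposite strand -> antisense;
3. same-strand overlap sharing at least one coding *exon* base -> sense;
4. remaining same-strand overlap (only intron bases touched) -> intronic.

Precedence is antisense > sense > intronic, so all opposite-strand overlaps are
antisense regardless of exon structure.  Coordinates are GTF 1-based inclusive
at the interface and converted to 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PROTEIN_CODING_SYNONYMS = {"protein_coding", "mrna", "coding", "protein-coding"}
LNCRNA_SYNONYMS = {"lncrna", "lincrna", "lnc_rna", "long_noncoding", "ncrna_long"}

#: biotype labels used throughout the package
BIOTYPE_MRNA = "protein_coding"
BIOTYPE_LNCRNA = "lncRNA"
BIOTYPE_TE = "te_insertion"


class GTFParseError(ValueError):
    """Raised on a malformed GTF line; message names the 1-based line number."""


@dataclass
class TranscriptRecord:
    """One annotated feature: mRNA transcript, lncRNA transcript or TE insertion.

    Coordinates are 1-based inclusive (GTF convention).  ``exons`` is a sorted,
    non-overlapping list of (start, end) pairs, all within [start, end].
    ``te_family`` is non-empty exactly when ``biotype == "te_insertion"``.
    """

    feature_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = BIOTYPE_MRNA
    te_family: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.feature_id}: bad strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.feature_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.feature_id}: overlapping exons")
            prev_end = e
        if (self.te_family != "") != (self.biotype == BIOTYPE_TE):
            raise ValueError(
                f"{self.feature_id}: te_family must be set iff biotype is te_insertion"
            )

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass(frozen=True)
class PositionalClass:
    """Positional category of one lncRNA or TE, with its coding evidence.

    ``evidence`` is the id of the protein-coding transcript justifying a
    sense/antisense/intronic call; empty for lincRNA/intergenic.
    """

    feature_id: str
    klass: str
    evidence: str = ""


@dataclass(frozen=True)
class FeatureStats:
    feature_id: str
    transcript_length: int
    n_exons: int


# ---------------------------------------------------------------------------
# GTF / TE annotation reading
# ---------------------------------------------------------------------------

def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _resolve_biotype(raw: str) -> str | None:
    low = raw.lower()
    if low in PROTEIN_CODING_SYNONYMS:
        return BIOTYPE_MRNA
    if low in LNCRNA_SYNONYMS:
        return BIOTYPE_LNCRNA
    if low in {"te", "te_insertion", "transposable_element"}:
        return BIOTYPE_TE
    return None


def _read_gtf_rows(path: str | Path):
    """Yield (line_number, fields, attrs) for feature rows of a GTF file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            yield lineno, fields, _parse_attributes(fields[8])


def read_annotation(
    gtf_path: str | Path,
    te_annotation_path: str | Path | None = None,
    te_family_map_path: str | Path | None = None,
) -> list[TranscriptRecord]:
    """Read transcripts (and optionally TE insertions) into TranscriptRecords.

    ``transcript_biotype`` (falling back to ``gene_biotype``) distinguishes
    protein-coding from lncRNA transcripts; unknown biotypes are dropped with a
    logged count.  Transcripts with no exon rows become single-exon records
    spanning their annotated range; exon rows without a transcript row have a
    record synthesized from the exon span (both logged).

    The TE annotation may be a GTF (family taken from ``te_family`` or
    ``gene_id``) or a 5-column TSV (insertion_id, chrom, start, end, strand)
    accompanied by ``te_family_map_path`` (insertion_id, family).
    """
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    exon_meta: dict[str, dict] = {}
    dropped = 0
    for lineno, fields, attrs in _read_gtf_rows(gtf_path):
        kind = fields[2]
        if kind not in {"transcript", "exon"}:
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            raise GTFParseError(
                f"{gtf_path}: malformed GTF line {lineno}: missing transcript_id"
            )
        start, end = int(fields[3]), int(fields[4])
        if kind == "transcript":
            raw_bt = attrs.get("transcript_biotype", attrs.get("gene_biotype", ""))
            biotype = _resolve_biotype(raw_bt)
            if biotype is None:
                dropped += 1
                continue
            spans[tid] = dict(
                gene_id=attrs.get("gene_id", tid),
                chrom=fields[0],
                start=start,
                end=end,
                strand=fields[6],
                biotype=biotype,
            )
        else:
            exons.setdefault(tid, []).append((start, end))
            exon_meta.setdefault(
                tid,
                dict(
                    chrom=fields[0],
                    strand=fields[6],
                    gene_id=attrs.get("gene_id", tid),
                    biotype=_resolve_biotype(
                        attrs.get("transcript_biotype", attrs.get("gene_biotype", ""))
                    )
                    or BIOTYPE_MRNA,
                ),
            )

    if dropped:
        logger.info("read_annotation: dropped %d transcripts with unknown biotype", dropped)

    records: list[TranscriptRecord] = []
    for tid, info in spans.items():
        ex = exons.get(tid)
        if not ex:
            logger.warning(
                "read_annotation: transcript %s has no exon rows; using its span", tid
            )
            ex = [(info["start"], info["end"])]
        records.append(
            TranscriptRecord(
                feature_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                exons=ex,
                biotype=info["biotype"],
            )
        )
    # exon rows whose transcript never appeared: synthesize from the exon span
    for tid, ex in exons.items():
        if tid in spans:
            continue
        logger.warning(
            "read_annotation: exon rows for %s lack a transcript row; synthesizing", tid
        )
        meta = exon_meta[tid]
        records.append(
            TranscriptRecord(
                feature_id=tid,
                gene_id=meta["gene_id"],
                chrom=meta["chrom"],
                start=min(s for s, _ in ex),
                end=max(e for _, e in ex),
                strand=meta["strand"],
                exons=sorted(ex),
                biotype=meta["biotype"],
            )
        )

    if te_annotation_path is not None:
        records.extend(read_te_annotation(te_annotation_path, te_family_map_path))
    return records


def read_te_annotation(
    path: str | Path, family_map_path: str | Path | None = None
) -> list[TranscriptRecord]:
    """Read TE insertions from GTF rows or a 5-column TSV + family map."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.count("\t") == 8:  # GTF rows
        out = []
        for lineno, fields, attrs in _read_gtf_rows(path):
            tid = attrs.get("transcript_id", attrs.get("insertion_id"))
            if tid is None:
                raise GTFParseError(
                    f"{path}: malformed TE GTF line {lineno}: missing transcript_id"
                )
            family = attrs.get("te_family", attrs.get("gene_id", ""))
            if fields[2] not in {"transcript", "te_insertion"}:
                continue
            out.append(
                TranscriptRecord(
                    feature_id=tid,
                    gene_id=family or tid,
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                    biotype=BIOTYPE_TE,
                    te_family=family or "unknown_family",
                )
            )
        return out
    # TSV form
    tbl = pd.read_csv(
        path, sep="\t", header=None,
        names=["insertion_id", "chrom", "start", "end", "strand"],
        dtype={"chrom": str},
    )
    if family_map_path is None:
        raise ValueError("TSV TE annotation requires a family map (insertion_id, family)")
    fam = pd.read_csv(family_map_path, sep="\t", header=None,
                      names=["insertion_id", "family"])
    fam_map = dict(zip(fam["insertion_id"], fam["family"]))
    missing = [i for i in tbl["insertion_id"] if i not in fam_map]
    if missing:
        raise ValueError(f"TE insertions missing from family map: {missing[:10]}")
    return [
        TranscriptRecord(
            feature_id=r.insertion_id,
            gene_id=fam_map[r.insertion_id],
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            biotype=BIOTYPE_TE,
            te_family=fam_map[r.insertion_id],
        )
        for r in tbl.itertuples()
    ]


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

def _spans_overlap(a: TranscriptRecord, b: TranscriptRecord) -> bool:
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def _shares_exon_base(a: TranscriptRecord, b: TranscriptRecord) -> bool:
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def _classify(
    feat: TranscriptRecord,
    coding: Sequence[TranscriptRecord],
    intergenic_label: str,
) -> PositionalClass:
    overlapping = [c for c in coding if _spans_overlap(feat, c)]
    if not overlapping:
        return PositionalClass(feat.feature_id, intergenic_label, "")
    anti = sorted(c.feature_id for c in overlapping if c.strand != feat.strand)
    if anti:
        return PositionalClass(feat.feature_id, "antisense", anti[0])
    sense = sorted(
        c.feature_id for c in overlapping
        if c.strand == feat.strand and _shares_exon_base(feat, c)
    )
    if sense:
        return PositionalClass(feat.feature_id, "sense", sense[0])
    # same-strand span overlap touching only intron bases
    intr = sorted(c.feature_id for c in overlapping)
    return PositionalClass(feat.feature_id, "intronic", intr[0])


def classify_lncrna(
    lnc: TranscriptRecord, coding: Sequence[TranscriptRecord]
) -> PositionalClass:
    """Classify one lncRNA as lincRNA / antisense / sense / intronic."""
    if lnc.biotype != BIOTYPE_LNCRNA:
        raise ValueError(f"{lnc.feature_id} is not a lncRNA")
    if not any(c.chrom == lnc.chrom for c in coding):
        logger.info("classify_lncrna: %s on %s has no coding neighbours", lnc.feature_id, lnc.chrom)
    return _classify(lnc, coding, "lincRNA")


def classify_te(te: TranscriptRecord, coding: Sequence[TranscriptRecord]) -> PositionalClass:
    """Classify one TE insertion as intergenic / antisense / sense / intronic."""
    if te.biotype != BIOTYPE_TE:
        raise ValueError(f"{te.feature_id} is not a TE insertion")
    return _classify(te, coding, "intergenic")


def classify_all(records: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Classify every lncRNA and TE against the coding transcripts.

    Returns a DataFrame (feature_id, biotype, klass, evidence), deterministic
    in the input order of the noncoding features.
    """
    coding = [r for r in records if r.biotype == BIOTYPE_MRNA]
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for c in coding:
        by_chrom.setdefault(c.chrom, []).append(c)
    rows = []
    for r in records:
        if r.biotype == BIOTYPE_LNCRNA:
            pc = classify_lncrna(r, by_chrom.get(r.chrom, []))
        elif r.biotype == BIOTYPE_TE:
            pc = classify_te(r, by_chrom.get(r.chrom, []))
        else:
            continue
        rows.append((pc.feature_id, r.biotype, pc.klass, pc.evidence))
    return pd.DataFrame(rows, columns=["feature_id", "biotype", "klass", "evidence"])


def feature_stats(records: Sequence[TranscriptRecord]) -> tuple[list[FeatureStats], pd.DataFrame]:
    """Per-feature exon count and summed exon length, plus per-biotype means."""
    if not records:
        raise ValueError("feature_stats: empty record list")
    stats = [
        FeatureStats(r.feature_id, r.transcript_length, r.n_exons) for r in records
    ]
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "biotype": [r.biotype for r in records],
            "transcript_length": [s.transcript_length for s in stats],
            "n_exons": [s.n_exons for s in stats],
        }
    )
    means = df.groupby("biotype")[["transcript_length", "n_exons"]].mean()
    return stats, means


def write_classification(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
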