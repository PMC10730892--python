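import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from aneutx import CountMatrix, KaryotypeSpec, SampleMeta, TranscriptRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def trisomy_pair():
    """Trisomy-2L female vs euploid female karyotypes."""
    aut = {"2L": 2, "2R": 2, "3L": 2, "3R": 2, "4": 2}
    control = KaryotypeSpec("CF", {"X": 2, **aut})
    case = KaryotypeSpec("2LF", {"X": 2, **aut, "2L": 3}, control_genotype="CF")
    return case, control


def make_matrix(values: dict[str, list[float]], features: list[str],
                genotypes: dict[str, str] | None = None, unit="raw_counts") -> CountMatrix:
    """Small CountMatrix helper: values maps sample_id -> column."""
    genotypes = genotypes or {}
    reps: dict[str, int] = {}
    samples = []
    for sid in values:
        g = genotypes.get(sid, sid)
        reps[g] = reps.get(g, 0) + 1
        samples.append(SampleMeta(sid, g, "F", reps[g]))
    df = pd.DataFrame(values, index=features)
    return CountMatrix(df, samples, unit)


@pytest.fixture
def toy_gtf(tmp_path):
    """Two-transcript GTF: one coding (2 exons), one lncRNA (1 exon)."""
    lines = [
        # coding transcript on 2L, +: exons 100-199 and 300-399
        '2L\tsrc\ttranscript\t100\t399\t.\t+\t.\tgene_id "g1"; transcript_id "tx1"; transcript_biotype "protein_coding";',
        '2L\tsrc\texon\t100\t199\t.\t+\t.\tgene_id "g1"; transcript_id "tx1"; transcript_biotype "protein_coding";',
        '2L\tsrc\texon\t300\t399\t.\t+\t.\tgene_id "g1"; transcript_id "tx1"; transcript_biotype "protein_coding";',
        # lncRNA on X, -: single exon
        'X\tsrc\ttranscript\t1000\t1500\t.\t-\t.\tgene_id "g2"; transcript_id "tx2"; transcript_biotype "lncRNA";',
        'X\tsrc\texon\t1000\t1500\t.\t-\t.\tgene_id "g2"; transcript_id "tx2"; transcript_biotype "lncRNA";',
    ]
    p = tmp_path / "toy.gtf"
    p.write_text("\n".join(lines) + "\n")
    return p


def coding_transcript(tid="c1", chrom="2L", start=1000, strand="+",
                      exon_len=1000, intron_len=999, n_exons=2) -> TranscriptRecord:
    """Coding transcript with regular exon/intron structure."""
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    return TranscriptRecord(tid, tid + "_g", chrom, start, exons[-1][1], strand,
                            exons, "protein_coding")
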