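"""Synthetic aneuploid transcriptome generator with planted dosage responses.

The generator emulates the study design the pipeline targets: five *Drosophila*
karyotypes — euploid female (CF) and male (CM) controls, trisomy-2L female
(2LF) and male (2LM), and metafemale (XXX) — with three replicates each, and
mRNA, lncRNA and TE-insertion features laid out on arms X, 2L, 2R, 3L, 3R, 4.

Every feature carries one planted dosage-response *type*:

* ratio-1 ("compensated" on a varied arm, "unchanged" elsewhere) — expression
  unaffected by the extra dose;
* "direct" / "dosage_effect" — expression proportional to the varied-arm dose
  (ratio 1.5 in a trisomy);
* "inverse" — expression inversely modulated by the varied dose (ratio 2/3).

Expected counts are mu(feature, sample) = base_mean * response(feature,
karyotype) * library_factor(sample); realized counts are negative-binomial
with variance mu + dispersion * mu**2 (dispersion 0 is the deterministic
noise-free limit, counts exactly mu).  Coordinates are emitted so that all
four positional classes (lincRNA/intronic/sense/antisense and the TE
equivalents) are present, and a truth table records every planted label.

A single numpy Generator seeded once drives all randomness; identical seeds
give byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    BIOTYPE_TE,
    TranscriptRecord,
)
from .imbalance import KaryotypeSpec, varied_arms
from .quantify import CountMatrix, SampleMeta

logger = logging.getLogger(__name__)

#: planted class label -> response type
RESPONSE_TYPE = {
    "compensated": "one",
    "unchanged": "one",
    "dosage_effect": "direct",
    "direct": "direct",
    "inverse": "inverse",
}

ARMS = {"X": 23_500_000, "2L": 23_000_000, "2R": 25_300_000,
        "3L": 28_100_000, "3R": 32_100_000, "4": 1_350_000}


def default_karyotypes() -> list[KaryotypeSpec]:
    """The five-genotype study design (arm doses per genotype)."""
    aut = {"2L": 2, "2R": 2, "3L": 2, "3R": 2, "4": 2}
    return [
        KaryotypeSpec("CF", {"X": 2, **aut}),
        KaryotypeSpec("CM", {"X": 1, **aut}),
        KaryotypeSpec("2LF", {"X": 2, **aut, "2L": 3}, control_genotype="CF"),
        KaryotypeSpec("2LM", {"X": 1, **aut, "2L": 3}, control_genotype="CM"),
        KaryotypeSpec("XXX", {"X": 3, **aut}, control_genotype="CF"),
    ]


def _default_fractions() -> dict:
    """Planted class mix per biotype and arm role, shaped after the observed
    ratio distributions: cis mRNA mostly compensated, cis lncRNA split between
    compensation and further inverse modulation, trans features dominated by
    the inverse effect (lncRNAs more than mRNAs)."""
    return {
        BIOTYPE_MRNA: {
            "cis": {"compensated": 0.70, "dosage_effect": 0.15, "inverse": 0.15},
            "trans": {"unchanged": 0.50, "inverse": 0.45, "direct": 0.05},
        },
        BIOTYPE_LNCRNA: {
            "cis": {"compensated": 0.40, "dosage_effect": 0.15, "inverse": 0.45},
            "trans": {"unchanged": 0.30, "inverse": 0.65, "direct": 0.05},
        },
        BIOTYPE_TE: {
            "cis": {"compensated": 0.40, "dosage_effect": 0.15, "inverse": 0.45},
            "trans": {"unchanged": 0.35, "inverse": 0.60, "direct": 0.05},
        },
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset; defaults encode the study design."""

    arms: dict[str, int] = dc_field(default_factory=lambda: dict(ARMS))
    n_mrna_per_arm: int = 80
    n_lncrna_per_arm: int = 24
    n_te_families: int = 12
    insertions_per_family: int = 5
    genotypes: list[KaryotypeSpec] = dc_field(default_factory=default_karyotypes)
    replicates: int = 3
    base_mean_log_mean: float = float(np.log(200.0))
    base_mean_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    class_fractions: dict = dc_field(default_factory=_default_fractions)
    lncrna_inverse_boost: float = 1.0
    library_factors: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for biotype, by_loc in self.class_fractions.items():
            for loc, fr in by_loc.items():
                bad = [k for k in fr if k not in RESPONSE_TYPE]
                if bad:
                    raise ValueError(f"unknown class labels {bad} for {biotype}/{loc}")
                if abs(sum(fr.values()) - 1.0) > 1e-9:
                    raise ValueError(f"class fractions for {biotype}/{loc} do not sum to 1")

    def cis_capable_arms(self) -> set[str]:
        """Arms varied in at least one aneuploid genotype of the design."""
        by_name = {k.genotype: k for k in self.genotypes}
        out: set[str] = set()
        for k in self.genotypes:
            if k.control_genotype:
                out.update(varied_arms(k, by_name[k.control_genotype]))
        return out


@dataclass
class SimulatedDataset:
    records: list[TranscriptRecord]
    counts: CountMatrix
    truth: pd.DataFrame
    config: SimulationConfig
    family_map: dict[str, str] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# coordinate scaffold
# ---------------------------------------------------------------------------

_GENE_PITCH = 50_000  # spacing between coding genes along an arm


def _coding_gene(arm: str, i: int) -> TranscriptRecord:
    s = 10_000 + i * _GENE_PITCH
    strand = "+" if i % 2 == 0 else "-"
    exons = [(s, s + 999), (s + 2000, s + 2499), (s + 3500, s + 3999)]
    tid = f"mrna_{arm}_{i:04d}"
    return TranscriptRecord(tid, f"gene_{arm}_{i:04d}", arm, s, s + 3999,
                            strand, exons, BIOTYPE_MRNA)


_LNC_CLASSES = ("lincRNA", "intronic", "sense", "antisense")
_TE_CLASSES = ("intergenic", "intronic", "sense", "antisense")


def _place_noncoding(
    arm: str, i: int, host: TranscriptRecord, klass: str, feature_id: str,
    biotype: str, te_family: str = "",
) -> TranscriptRecord:
    """Place one lncRNA/TE so it realizes the requested positional class
    relative to its host coding gene (exons at +0..999, introns at
    +1000..1999 and +2500..3499 of the host start)."""
    s = host.start
    flip = {"+": "-", "-": "+"}
    if klass in ("lincRNA", "intergenic"):
        start, end, strand = s + 20_000, s + 21_000, "+"
    elif klass == "intronic":
        start, end, strand = s + 1200, s + 1800, host.strand
    elif klass == "sense":
        start, end, strand = s + 800, s + 1300, host.strand
    else:  # antisense
        start, end, strand = s + 800, s + 1300, flip[host.strand]
    return TranscriptRecord(
        feature_id, feature_id, arm, start, end, strand,
        [(start, end)], biotype, te_family,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + a*mu^2); dispersion 0 is the deterministic limit."""
    if dispersion == 0:
        return mu.copy()
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mu)
    return rng.negative_binomial(n, p, size=mu.shape).astype(float)


def _expected_ratio(
    rtype: str, chrom: str, case: KaryotypeSpec, control: KaryotypeSpec,
    boost: float = 1.0,
) -> float:
    """Expected case/control ratio for one feature under one comparison."""
    ratio = 1.0
    for arm in varied_arms(case, control):
        dose = case.doses[arm] / control.doses[arm]
        if rtype == "direct":
            ratio *= dose
        elif rtype == "inverse":
            ratio *= boost / dose
    return ratio


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate annotation, raw counts, metadata and the planted truth table."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    by_name = {k.genotype: k for k in config.genotypes}
    cis_arms = config.cis_capable_arms()

    records: list[TranscriptRecord] = []
    feature_info: list[dict] = []  # feature_id, biotype, chrom, planted label
    family_map: dict[str, str] = {}

    for arm in config.arms:
        coding = [_coding_gene(arm, i) for i in range(config.n_mrna_per_arm)]
        records.extend(coding)
        loc = "cis" if arm in cis_arms else "trans"
        for rec in coding:
            feature_info.append(dict(feature_id=rec.feature_id,
                                     biotype=BIOTYPE_MRNA, chrom=arm,
                                     location_role=loc, positional_class=""))
        for j in range(config.n_lncrna_per_arm):
            klass = _LNC_CLASSES[j % 4]
            host = coding[j % len(coding)]
            fid = f"lnc_{arm}_{j:04d}"
            records.append(_place_noncoding(arm, j, host, klass, fid, BIOTYPE_LNCRNA))
            feature_info.append(dict(feature_id=fid, biotype=BIOTYPE_LNCRNA,
                                     chrom=arm, location_role=loc,
                                     positional_class=klass))

    # TE insertions: families spread across arms
    arm_names = list(config.arms)
    idx = 0
    for f in range(config.n_te_families):
        family = f"TEfam_{f:03d}"
        for k in range(config.insertions_per_family):
            arm = arm_names[idx % len(arm_names)]
            klass = _TE_CLASSES[idx % 4]
            host = _coding_gene(arm, (idx * 7) % config.n_mrna_per_arm)
            fid = f"te_{family}_{k}"
            records.append(_place_noncoding(arm, idx, host, klass, fid,
                                            BIOTYPE_TE, te_family=family))
            family_map[fid] = family
            loc = "cis" if arm in cis_arms else "trans"
            feature_info.append(dict(feature_id=fid, biotype=BIOTYPE_TE,
                                     chrom=arm, location_role=loc,
                                     positional_class=klass))
            idx += 1

    info = pd.DataFrame(feature_info)
    n_feat = len(info)

    # planted dosage class per feature
    planted = []
    for row in info.itertuples():
        fr = config.class_fractions[row.biotype][row.location_role]
        labels = sorted(fr)
        planted.append(rng.choice(labels, p=[fr[l] for l in labels]))
    info["planted_class"] = planted
    info["response_type"] = info["planted_class"].map(RESPONSE_TYPE)

    # base means
    base_mean = rng.lognormal(config.base_mean_log_mean,
                              config.base_mean_log_sd, size=n_feat)

    # samples
    samples = [
        SampleMeta(f"{k.genotype}{r}", k.genotype,
                   "M" if k.genotype.endswith("M") else "F", r)
        for k in config.genotypes
        for r in range(1, config.replicates + 1)
    ]

    # expected ratio per genotype
    exp_ratio = pd.DataFrame(index=info["feature_id"])
    for k in config.genotypes:
        if not k.control_genotype:
            exp_ratio[k.genotype] = 1.0
            continue
        control = by_name[k.control_genotype]
        vals = []
        for row in info.itertuples():
            boost = (config.lncrna_inverse_boost
                     if row.biotype == BIOTYPE_LNCRNA else 1.0)
            vals.append(_expected_ratio(row.response_type, row.chrom, k, control, boost))
        exp_ratio[k.genotype] = vals

    mu = np.empty((n_feat, len(samples)))
    lib = config.library_factors or {}
    for j, s in enumerate(samples):
        mu[:, j] = base_mean * exp_ratio[s.genotype].to_numpy() * lib.get(s.sample_id, 1.0)
    values = _draw_counts(rng, mu, config.nb_dispersion)

    counts = CountMatrix(
        pd.DataFrame(values, index=info["feature_id"].to_list(),
                     columns=[s.sample_id for s in samples]),
        samples,
    )
    truth = info.copy()
    for k in config.genotypes:
        truth[f"expected_ratio_{k.genotype}"] = exp_ratio[k.genotype].to_numpy()
    return SimulatedDataset(records, counts, truth, config, family_map)


# ---------------------------------------------------------------------------
# landmark simulation (pure-class calibration datasets)
# ---------------------------------------------------------------------------

def simulate_landmark_dataset(
    planted_class: str,
    location: str = "cis",
    n_features: int = 2000,
    base_mean: float = 500.0,
    dispersion: float = 0.05,
    replicates: int = 3,
    case_dose: int = 3,
    control_dose: int = 2,
    seed: int = 1,
    n_anchor: int = 20_000,
    anchor_mean: float = 25_000.0,
):
    """Simulate one pure dosage-response class plus a stable anchor background.

    All ``n_features`` target features carry ``planted_class`` (on the varied
    arm for ``location="cis"``, on an unvaried arm otherwise).  Because CPM
    only measures library *composition*, a uniformly shifted feature set would
    be renormalized away; the anchor background (expression-stable features
    dominating ~99.6% of the library) pins the per-sample totals so the
    planted landmark survives CPM normalization.

    Returns ``(counts, case_samples, control_samples, target_ids,
    expected_ratio)`` with counts in raw units.
    """
    rtype = RESPONSE_TYPE[planted_class]
    dose = case_dose / control_dose
    if rtype == "direct":
        expected = dose
    elif rtype == "inverse":
        expected = 1.0 / dose
    else:
        expected = 1.0
    rng = np.random.default_rng(seed)
    target_arm = "2L" if location == "cis" else "X"
    target_ids = [f"target_{i:05d}" for i in range(n_features)]
    anchor_ids = [f"anchor_{i:05d}" for i in range(n_anchor)]
    case_samples = [f"case{r}" for r in range(1, replicates + 1)]
    control_samples = [f"control{r}" for r in range(1, replicates + 1)]
    mu_ctrl = np.concatenate([
        np.full(n_features, base_mean), np.full(n_anchor, anchor_mean),
    ])
    mu_case = np.concatenate([
        np.full(n_features, base_mean * expected), np.full(n_anchor, anchor_mean),
    ])
    cols = {}
    for s in case_samples:
        cols[s] = _draw_counts(rng, mu_case, dispersion)
    for s in control_samples:
        cols[s] = _draw_counts(rng, mu_ctrl, dispersion)
    samples = [SampleMeta(s, "case", "F", r + 1) for r, s in enumerate(case_samples)]
    samples += [SampleMeta(s, "control", "F", r + 1) for r, s in enumerate(control_samples)]
    counts = CountMatrix(
        pd.DataFrame(cols, index=target_ids + anchor_ids), samples
    )
    logger.info(
        "simulate_landmark_dataset: %s/%s expected ratio %.4f",
        planted_class, location, expected,
    )
    return counts, case_samples, control_samples, target_ids, expected


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(truth: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Compare classified dosage labels against the planted truth.

    ``truth`` needs (feature_id, planted_class); ``labels`` needs
    (feature_id, klass).  Labels are matched at the response-type level, so
    "compensated" and "unchanged" (both ratio-1) count as the same call, as do
    "dosage_effect" and "direct".  Returns overall and per-class accuracy plus
    a confusion table.
    """
    merged = truth.merge(labels, on="feature_id", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("evaluate_recovery: feature sets do not match")
    t = merged["planted_class"].map(RESPONSE_TYPE)
    c = merged["klass"].map(lambda k: RESPONSE_TYPE.get(k, "other"))
    correct = (t == c)
    per_class = {
        cls: float(correct[t == cls].mean()) for cls in sorted(t.unique())
    }
    confusion = pd.crosstab(t, c, rownames=["planted"], colnames=["called"])
    return {
        "overall": float(correct.mean()),
        "per_class": per_class,
        "confusion": confusion,
        "n": int(len(merged)),
    }


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write GTF, TE TSV + family map, counts, metadata, truth and config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "te": outdir / "te_insertions.tsv",
        "family_map": outdir / "te_families.tsv",
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.yaml",
    }
    with open(paths["gtf"], "w") as fh:
        for r in ds.records:
            if r.biotype == BIOTYPE_TE:
                continue
            bt = "protein_coding" if r.biotype == BIOTYPE_MRNA else "lncRNA"
            attrs = (f'gene_id "{r.gene_id}"; transcript_id "{r.feature_id}"; '
                     f'transcript_biotype "{bt}";')
            fh.write("\t".join([r.chrom, "sim", "transcript", str(r.start),
                                str(r.end), ".", r.strand, ".", attrs]) + "\n")
            for s, e in r.exons:
                fh.write("\t".join([r.chrom, "sim", "exon", str(s), str(e),
                                    ".", r.strand, ".", attrs]) + "\n")
    tes = [r for r in ds.records if r.biotype == BIOTYPE_TE]
    with open(paths["te"], "w") as fh:
        for r in tes:
            fh.write(f"{r.feature_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\n")
    with open(paths["family_map"], "w") as fh:
        for r in tes:
            fh.write(f"{r.feature_id}\t{r.te_family}\n")
    ds.counts.values.to_csv(paths["counts"], sep="\t")
    pd.DataFrame(
        [(s.sample_id, s.genotype, s.sex, s.replicate) for s in ds.counts.samples],
        columns=["sample_id", "genotype", "sex", "replicate"],
    ).to_csv(paths["metadata"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = ds.config
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "seed": cfg.seed,
                "replicates": cfg.replicates,
                "nb_dispersion": cfg.nb_dispersion,
                "n_mrna_per_arm": cfg.n_mrna_per_arm,
                "n_lncrna_per_arm": cfg.n_lncrna_per_arm,
                "n_te_families": cfg.n_te_families,
                "insertions_per_family": cfg.insertions_per_family,
                "lncrna_inverse_boost": cfg.lncrna_inverse_boost,
                "genotypes": {
                    k.genotype: {"doses": k.doses, "control": k.control_genotype}
                    for k in cfg.genotypes
                },
            },
            fh, sort_keys=True,
        )
    return paths
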