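"""Synthetic study generator with known ground truth.

Emulates the inputs of a multi-cohort rare-CNV burden study: a small
diploid genome with annotation tracks (centromeres/telomeres, an Ig/TCR
locus, segmental duplications, isoform-resolved gene models, labelled NDD
CNV regions), per-subject true CNVs, two deliberately discordant caller
outputs per sample (boundary jitter, fragmentation, false calls, gain/loss
flips), per-sample array-quality metrics, and phenotypes produced by a
linear liability model with planted effects:

    latent = intercept + beta_ndd_del * (NDD deletion Mb)
           + beta_geneset * (target gene-set count) + PC effects
           + beta_prs * PRS + Normal(0, noise_sd),  truncated to [0, 1]

Score cohorts report the latent value mapped onto their instrument's
theoretical range; case/control cohorts dichotomise it at a liability
cutoff. All randomness flows from a single seed through named
``numpy.random.SeedSequence`` spawns, so generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotation import AnnotationBundle
from .burden import BurdenEncoder
from .consensus import count_probes

__all__ = [
    "CallerErrorModel",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_annotation",
    "generate_truth",
    "generate_callsets",
    "generate_qc_metrics",
    "generate_phenotypes",
    "simulate_study",
    "write_fixtures",
]

#: theoretical instrument ranges cycled across score cohorts (PCL-style 17-85,
#: CAPS-style 0-136, PSS-style 0-51, IES-style 0-88)
ASSESSMENT_RANGES = [(17.0, 85.0), (0.0, 136.0), (0.0, 51.0), (0.0, 88.0)]

_TEL_LEN = 100_000
_CEN_LEN = 1_000_000
_MIN_TRUE_LEN = 30_000
_MAX_TRUE_LEN = 600_000
_MIN_SAME_TYPE_GAP = 1_000_000  # keeps distinct true CNVs un-annealable


@dataclass
class CallerErrorModel:
    """Error structure of one synthetic caller (both callers share it)."""

    jitter_sd: float = 2_000.0        # bp SD of independent boundary noise
    fragmentation_prob: float = 0.10  # split a true CNV into two sub-calls
    false_call_rate: float = 0.20     # expected spurious calls per subject
    type_flip_prob: float = 0.01      # report DEL as DUP or vice versa

    def __post_init__(self) -> None:
        for name in ("fragmentation_prob", "type_flip_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.jitter_sd < 0 or self.false_call_rate < 0:
            raise ValueError("jitter_sd and false_call_rate must be >= 0")


@dataclass
class SyntheticConfig:
    """Study-generation parameters (defaults define the study conditions)."""

    n_cohorts: int = 5
    subjects_per_cohort: int = 1000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 25_000_000}
    )
    probe_spacing: int = 1_000
    ndd_regions: list[dict] | None = None  # default layout when None
    gene_count: int = 200
    segdup_fraction: float = 0.03
    true_cnv_rate: float = 1.6      # expected background CNVs per subject
    ndd_cnv_rate: float = 0.08      # probability a subject carries an NDD CNV
    beta_ndd_del: float = 0.03      # per Mb of NDD deletion, on the 0-1 scale
    beta_geneset: float = 0.0       # per gene hit in the target set
    target_geneset: str = "neuro_target"
    beta_prs: float = 0.011         # per SD of PRS
    pc_betas: tuple[float, ...] = (0.01, -0.008, 0.006, -0.004, 0.002)
    intercept: float = 0.45
    noise_sd: float = 0.12
    caller_error: CallerErrorModel = field(default_factory=CallerErrorModel)
    case_threshold: float = 0.62    # liability cutoff for case/control cohorts
    n_case_control_cohorts: int = 1
    qc_outlier_rate: float = 0.002
    genotype_fail_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1 or self.subjects_per_cohort < 1:
            raise ValueError("need at least one cohort and one subject")
        for name, v in self.chrom_lengths.items():
            if v <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        for name in ("segdup_fraction", "ndd_cnv_rate", "qc_outlier_rate", "genotype_fail_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.true_cnv_rate < 0:
            raise ValueError("true_cnv_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.case_threshold <= 1:
            raise ValueError("case_threshold must be in [0, 1]")
        if self.n_case_control_cohorts > self.n_cohorts:
            raise ValueError("more case/control cohorts than cohorts")
        if self.ndd_regions is not None:
            for r in self.ndd_regions:
                chrom = r["chrom"]
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"NDD region {r['label']!r} on unknown chromosome {chrom!r}")
                if r["end"] > self.chrom_lengths[chrom] or r["start"] < 0:
                    raise ValueError(
                        f"NDD region {r['label']!r} exceeds chromosome {chrom} "
                        f"(length {self.chrom_lengths[chrom]})"
                    )

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """Planted truth: the true CNVs, effects and latent phenotypes."""

    cnvs: pd.DataFrame            # sample_id, chrom, start, end, cnv_type, truth_id
    subjects: pd.DataFrame        # sample_id, cohort_id
    true_betas: dict[str, float] = field(default_factory=dict)
    latent: pd.Series | None = None


@dataclass
class SyntheticStudy:
    """Everything the pipeline consumes, plus its ground truth."""

    config: SyntheticConfig
    annotation: AnnotationBundle
    truth: GroundTruth
    callsets: pd.DataFrame        # both callers, canonical call columns + origin
    qc_metrics: pd.DataFrame
    subjects: pd.DataFrame        # phenotypes + covariates


# -- annotation ------------------------------------------------------------


def _default_ndd_layout(chrom_lengths: dict[str, int]) -> list[dict]:
    # one del and one dup region per chromosome minimum, away from the
    # centromere (middle) and telomeres (ends)
    regions = []
    fractions = [
        (0.08, "DEL"), (0.16, "DUP"), (0.24, "DEL"),
        (0.32, "DUP"), (0.62, "DEL"), (0.78, "DUP"),
    ]
    sizes = [400_000, 450_000, 500_000, 550_000]
    for ci, (chrom, length) in enumerate(sorted(chrom_lengths.items())):
        for ri, ((frac, cnv_type), size) in enumerate(
            zip(fractions, sizes * (1 + len(fractions) // len(sizes)))
        ):
            start = int(frac * length)
            typ = cnv_type if ci % 2 == 0 else ("DUP" if cnv_type == "DEL" else "DEL")
            regions.append(
                {
                    "label": f"{chrom}_ndd{ri + 1}_{typ.lower()}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + size,
                    "cnv_type": typ,
                }
            )
    return regions


def generate_annotation(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> AnnotationBundle:
    """Build the annotation bundle (probe map, tracks, genes, NDD regions)."""
    rng = rng or config.rng(0)
    chroms = sorted(config.chrom_lengths)
    probes = {
        c: np.arange(0, config.chrom_lengths[c], config.probe_spacing, dtype=np.int64)
        for c in chroms
    }

    special_rows = []
    for c in chroms:
        L = config.chrom_lengths[c]
        special_rows.append((c, 0, min(_TEL_LEN, L), "telomere"))
        if L > 2 * _TEL_LEN:
            special_rows.append((c, L - _TEL_LEN, L, "telomere"))
        if L > 4 * _CEN_LEN:
            mid = L // 2
            special_rows.append((c, mid - _CEN_LEN // 2, mid + _CEN_LEN // 2, "centromere"))
    last = chroms[-1]
    ig_start = int(0.85 * config.chrom_lengths[last])
    special_rows.append((last, ig_start, ig_start + 200_000, "ig_tcr"))
    special = pd.DataFrame(special_rows, columns=["chrom", "start", "end", "name"])

    ndd = pd.DataFrame(config.ndd_regions or _default_ndd_layout(config.chrom_lengths))
    ndd = ndd[["label", "chrom", "start", "end", "cnv_type"]]

    segdups = _place_segdups(config, special, ndd, rng)
    isoforms = _place_genes(config, rng)
    genesets = _build_genesets(isoforms, rng, config.target_geneset)
    return AnnotationBundle(
        chrom_lengths=dict(config.chrom_lengths),
        probes=probes,
        special=special,
        segdups=segdups,
        ndd_regions=ndd,
        isoforms=isoforms,
        genesets=genesets,
    )


def _place_segdups(config, special, ndd, rng) -> pd.DataFrame:
    rows = []
    if config.segdup_fraction > 0:
        genome = sum(config.chrom_lengths.values())
        target = config.segdup_fraction * genome
        chroms = sorted(config.chrom_lengths)
        weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        placed = 0
        avoid = pd.concat(
            [special[["chrom", "start", "end"]], ndd[["chrom", "start", "end"]]],
            ignore_index=True,
        )
        attempts = 0
        while placed < target and attempts < 100_000:
            attempts += 1
            c = rng.choice(chroms, p=weights)
            length = int(rng.integers(20_000, 200_000))
            start = int(rng.integers(0, config.chrom_lengths[c] - length))
            a = avoid[avoid["chrom"] == c]
            if ((a["start"] < start + length) & (a["end"] > start)).any():
                continue
            rows.append((c, start, start + length))
            placed += length
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _place_genes(config, rng) -> pd.DataFrame:
    chroms = sorted(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    for i in range(config.gene_count):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(np.exp(rng.uniform(np.log(5_000), np.log(150_000))))
        start = int(rng.integers(0, config.chrom_lengths[c] - length))
        symbol = f"G{i + 1:04d}"
        coding = (i % 10) != 9  # every 10th gene is non-coding (NR_ accession)
        prefix = "NM" if coding else "NR"
        if i == 0:
            # guaranteed multi-isoform gene: collapsed span is min-start to max-end
            mid = start + length // 2
            rows.append((symbol, c, start, mid + length // 4, f"{prefix}_{i:05d}.1"))
            rows.append((symbol, c, start + length // 4, start + length, f"{prefix}_{i:05d}.2"))
        else:
            rows.append((symbol, c, start, start + length, f"{prefix}_{i:05d}.1"))
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "accession"])


def _build_genesets(isoforms, rng, target_name) -> dict[str, tuple[str, list[str]]]:
    coding = sorted(
        isoforms.loc[isoforms["accession"].str.startswith("NM_"), "symbol"].unique()
    )
    pool = list(coding)
    rng.shuffle(pool)

    def take(n):
        nonlocal pool
        out, pool = pool[:n], pool[n:]
        return sorted(out)

    return {
        target_name: ("neuro", take(30)),
        "control_matched": ("control", take(30)),
        "brain_expr_1": ("brain_expression", take(40)),
        "lof_intolerant": ("lof_intolerant", take(40)),
        "scrna_1": ("scRNA", take(20)),
    }


# -- true CNVs -------------------------------------------------------------


def _subject_roster(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for ci in range(config.n_cohorts):
        cohort = f"COH{ci + 1:02d}"
        for si in range(config.subjects_per_cohort):
            rows.append((f"{cohort}_S{si + 1:05d}", cohort))
    return pd.DataFrame(rows, columns=["sample_id", "cohort_id"])


def generate_truth(
    annotation: AnnotationBundle,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Plant per-subject true CNVs: background events plus NDD-region events.

    Background CNVs avoid special regions, segmental duplications and NDD
    regions (with a 1 Mb margin) so that the planted NDD burden is carried
    only by the dedicated NDD events, and same-type events within a subject
    are kept >= 1 Mb apart so that annealing cannot merge distinct truths.
    """
    rng = rng or config.rng(1)
    subjects = _subject_roster(config)
    n = len(subjects)
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    counts = rng.poisson(config.true_cnv_rate, n)
    total = int(counts.sum())
    sub_idx = np.repeat(np.arange(n), counts)
    chrom_idx = rng.choice(len(chroms), size=total, p=weights)
    lens = np.exp(rng.uniform(np.log(_MIN_TRUE_LEN), np.log(_MAX_TRUE_LEN), total)).astype(np.int64)
    max_start = lengths[chrom_idx].astype(np.int64) - lens
    starts = (rng.random(total) * np.maximum(max_start, 1)).astype(np.int64)
    types = np.where(rng.random(total) < 0.55, "DEL", "DUP")

    bg = pd.DataFrame(
        {
            "sample_id": subjects["sample_id"].to_numpy()[sub_idx],
            "chrom": np.array(chroms, dtype=object)[chrom_idx],
            "start": starts,
            "end": starts + lens,
            "cnv_type": types,
        }
    )
    avoid = pd.concat(
        [
            annotation.special[["chrom", "start", "end"]],
            annotation.segdups[["chrom", "start", "end"]],
            annotation.ndd_regions[["chrom", "start", "end"]].assign(
                start=lambda d: d["start"] - _MIN_SAME_TYPE_GAP,
                end=lambda d: d["end"] + _MIN_SAME_TYPE_GAP,
            ),
        ],
        ignore_index=True,
    )
    keep = np.ones(len(bg), dtype=bool)
    for c in chroms:
        a = avoid[avoid["chrom"] == c]
        m = bg["chrom"].to_numpy() == c
        if not m.any() or not len(a):
            continue
        s = bg["start"].to_numpy()[m][:, None]
        e = bg["end"].to_numpy()[m][:, None]
        hit = ((s < a["end"].to_numpy()[None, :]) & (e > a["start"].to_numpy()[None, :])).any(axis=1)
        keep[np.flatnonzero(m)[hit]] = False
    bg = bg.loc[keep]

    carrier = rng.random(n) < config.ndd_cnv_rate
    regions = annotation.ndd_regions.reset_index(drop=True)
    ridx = rng.integers(0, len(regions), size=int(carrier.sum()))
    ml = rng.integers(0, 50_000, size=len(ridx))
    mr = rng.integers(0, 50_000, size=len(ridx))
    reg = regions.iloc[ridx]
    ndd_events = pd.DataFrame(
        {
            "sample_id": subjects["sample_id"].to_numpy()[carrier],
            "chrom": reg["chrom"].to_numpy(),
            "start": np.maximum(reg["start"].to_numpy() - ml, 0),
            "end": np.minimum(
                reg["end"].to_numpy() + mr,
                np.array([config.chrom_lengths[c] for c in reg["chrom"]]),
            ),
            "cnv_type": reg["cnv_type"].to_numpy(),
        }
    )
    cnvs = pd.concat([bg, ndd_events], ignore_index=True)
    cnvs = cnvs.sort_values(["sample_id", "cnv_type", "chrom", "start"]).reset_index(drop=True)
    # enforce the same-type separation within subjects (iterate until stable)
    while True:
        s = cnvs["start"].to_numpy()
        e = cnvs["end"].to_numpy()
        same = (
            (cnvs["sample_id"].to_numpy()[1:] == cnvs["sample_id"].to_numpy()[:-1])
            & (cnvs["cnv_type"].to_numpy()[1:] == cnvs["cnv_type"].to_numpy()[:-1])
            & (cnvs["chrom"].to_numpy()[1:] == cnvs["chrom"].to_numpy()[:-1])
        )
        close = np.zeros(len(cnvs), dtype=bool)
        close[1:] = same & (s[1:] < e[:-1] + _MIN_SAME_TYPE_GAP)
        if not close.any():
            break
        cnvs = cnvs.loc[~close].reset_index(drop=True)
    cnvs = cnvs.sort_values(["sample_id", "chrom", "cnv_type", "start"]).reset_index(drop=True)
    cnvs["truth_id"] = np.arange(len(cnvs))
    return GroundTruth(cnvs=cnvs, subjects=subjects)


# -- caller emulation ------------------------------------------------------


def generate_callsets(
    truth: GroundTruth,
    annotation: AnnotationBundle,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    callers: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Emit two noisy per-sample callsets derived from the true CNVs.

    Each caller independently jitters boundaries, occasionally fragments a
    call into two pieces separated by a gap below the annealing threshold,
    flips a call's type, and adds false calls drawn uniformly over the
    non-centromeric genome with log-uniform lengths (10 kb - 1 Mb). Every
    row's ``origin`` column is either ``true:<truth_id>`` or ``false``.
    """
    rng = rng or config.rng(2)
    err = config.caller_error
    parts = []
    for caller in callers:
        t = truth.cnvs
        m = len(t)
        starts = t["start"].to_numpy().astype(np.int64)
        ends = t["end"].to_numpy().astype(np.int64)
        if err.jitter_sd > 0 and m:
            starts = starts + np.round(rng.normal(0, err.jitter_sd, m)).astype(np.int64)
            ends = ends + np.round(rng.normal(0, err.jitter_sd, m)).astype(np.int64)
        chrom_len = t["chrom"].map(config.chrom_lengths).to_numpy(dtype=np.int64)
        starts = np.clip(starts, 0, chrom_len - 1)
        ends = np.clip(ends, starts + 1_000, chrom_len)
        types = t["cnv_type"].to_numpy().copy()
        if err.type_flip_prob > 0 and m:
            flip = rng.random(m) < err.type_flip_prob
            types[flip] = np.where(types[flip] == "DEL", "DUP", "DEL")
        lens = ends - starts
        frag = (
            (rng.random(m) < err.fragmentation_prob) & (lens >= 20_000)
            if m
            else np.zeros(0, dtype=bool)
        )
        whole = pd.DataFrame(
            {
                "sample_id": t["sample_id"].to_numpy()[~frag],
                "chrom": t["chrom"].to_numpy()[~frag],
                "start": starts[~frag],
                "end": ends[~frag],
                "cnv_type": types[~frag],
                "origin": [f"true:{i}" for i in t["truth_id"].to_numpy()[~frag]],
            }
        )
        nf = int(frag.sum())
        frag_rows = []
        if nf:
            fs, fe = starts[frag], ends[frag]
            fl = fe - fs
            gap_frac = rng.uniform(0.05, 0.25, nf)
            gap_len = np.maximum((gap_frac * fl).astype(np.int64), 1)
            u = rng.uniform(0.10, 0.85 - gap_frac)
            gap_start = fs + (u * fl).astype(np.int64)
            ids = t["truth_id"].to_numpy()[frag]
            for piece_s, piece_e in [(fs, gap_start), (gap_start + gap_len, fe)]:
                frag_rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": t["sample_id"].to_numpy()[frag],
                            "chrom": t["chrom"].to_numpy()[frag],
                            "start": piece_s,
                            "end": piece_e,
                            "cnv_type": types[frag],
                            "origin": [f"true:{i}" for i in ids],
                        }
                    )
                )
        false_calls = _false_calls(truth.subjects, annotation, config, rng)
        pieces = [p for p in [whole] + frag_rows + [false_calls] if len(p)]
        cs = pd.concat(pieces, ignore_index=True) if pieces else whole
        cs["caller"] = caller
        parts.append(cs)
    calls = pd.concat(parts, ignore_index=True)
    calls["start"] = calls["start"].astype(np.int64)
    calls["end"] = calls["end"].astype(np.int64)
    calls = calls.sort_values(["caller", "sample_id", "chrom", "start"]).reset_index(drop=True)
    calls["n_probes"] = count_probes(calls, annotation.probes)
    calls["confidence"] = np.round(rng.uniform(10, 100, len(calls)), 2)
    return calls[
        ["sample_id", "chrom", "start", "end", "cnv_type", "n_probes", "caller", "confidence", "origin"]
    ]


def _false_calls(subjects, annotation, config, rng) -> pd.DataFrame:
    rate = config.caller_error.false_call_rate
    cols = ["sample_id", "chrom", "start", "end", "cnv_type", "origin"]
    if rate <= 0:
        return pd.DataFrame(columns=cols)
    n = len(subjects)
    counts = rng.poisson(rate, n)
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=cols)
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    sub_idx = np.repeat(np.arange(n), counts)
    chrom_idx = rng.choice(len(chroms), size=total, p=weights)
    lens = np.exp(rng.uniform(np.log(10_000), np.log(1_000_000), total)).astype(np.int64)
    max_start = lengths[chrom_idx].astype(np.int64) - lens
    starts = (rng.random(total) * np.maximum(max_start, 1)).astype(np.int64)
    df = pd.DataFrame(
        {
            "sample_id": subjects["sample_id"].to_numpy()[sub_idx],
            "chrom": np.array(chroms, dtype=object)[chrom_idx],
            "start": starts,
            "end": starts + lens,
            "cnv_type": np.where(rng.random(total) < 0.5, "DEL", "DUP"),
            "origin": "false",
        }
    )
    cen = annotation.special[annotation.special["name"] == "centromere"]
    keep = np.ones(len(df), dtype=bool)
    for _, r in cen.iterrows():
        keep &= ~(
            (df["chrom"].to_numpy() == r["chrom"])
            & (df["start"].to_numpy() < r["end"])
            & (df["end"].to_numpy() > r["start"])
        )
    return df.loc[keep, cols]


# -- QC metrics and phenotypes ---------------------------------------------


def generate_qc_metrics(
    subjects: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample array quality metrics and genotype-QC flags."""
    rng = rng or config.rng(3)
    n = len(subjects)
    out = pd.DataFrame(
        {
            "sample_id": subjects["sample_id"].to_numpy(),
            "cohort_id": subjects["cohort_id"].to_numpy(),
            "lrr_sd": np.clip(rng.normal(0.12, 0.02, n), 0.01, None),
            "baf_sd": np.clip(rng.normal(0.04, 0.008, n), 0.005, None),
            "waviness": np.abs(rng.normal(0.03, 0.01, n)),
        }
    )
    bad = rng.random(n) < config.qc_outlier_rate
    for col in ("lrr_sd", "baf_sd", "waviness"):
        out.loc[bad, col] *= 6.0
    for flag in ("missingness", "heterozygosity", "sex_check", "relatedness"):
        out[f"genotype_qc_{flag}"] = rng.random(n) >= config.genotype_fail_rate
    return out


def generate_phenotypes(
    truth: GroundTruth,
    burdens: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phenotypes and covariates under the planted linear liability model.

    ``burdens`` is the per-subject *true* burden table (indexed by
    sample_id) providing ``span_ndd_del_mb`` and, when a gene-set effect is
    planted, the target set's count column.
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng or config.rng(4)
    subjects = truth.subjects.copy()
    n = len(subjects)
    pcs = rng.standard_normal((n, 5))
    prs = rng.standard_normal(n)
    burden = burdens.reindex(subjects["sample_id"]).fillna(0.0)
    ndd_del = burden["span_ndd_del_mb"].to_numpy(dtype=float)
    latent = (
        config.intercept
        + config.beta_ndd_del * ndd_del
        + pcs @ np.asarray(config.pc_betas, dtype=float)
        + config.beta_prs * prs
        + rng.normal(0, config.noise_sd, n)
    )
    true_betas = {"span_ndd_del_mb": config.beta_ndd_del, "prs": config.beta_prs}
    if config.beta_geneset != 0.0:
        col = f"geneset__{config.target_geneset}"
        latent = latent + config.beta_geneset * burden[col].to_numpy(dtype=float)
        true_betas[col] = config.beta_geneset
    latent = np.clip(latent, 0.0, 1.0)

    cohorts = sorted(subjects["cohort_id"].unique())
    cc_cohorts = set(cohorts[len(cohorts) - config.n_case_control_cohorts:]) if config.n_case_control_cohorts else set()
    lo = np.empty(n)
    hi = np.empty(n)
    is_cc = np.zeros(n, dtype=bool)
    for i, cohort in enumerate(cohorts):
        m = (subjects["cohort_id"] == cohort).to_numpy()
        if cohort in cc_cohorts:
            is_cc[m] = True
            lo[m], hi[m] = 0.0, 1.0
        else:
            lo[m], hi[m] = ASSESSMENT_RANGES[i % len(ASSESSMENT_RANGES)]
    raw = np.where(is_cc, np.nan, lo + latent * (hi - lo))
    case = np.where(is_cc, (latent > config.case_threshold).astype(float), np.nan)

    out = subjects.assign(
        is_case_control=is_cc,
        assessment_min=lo,
        assessment_max=hi,
        phenotype_raw=raw,
        case=case,
        prs=prs,
    )
    for j in range(5):
        out[f"PC{j + 1}"] = pcs[:, j]
    truth.true_betas = true_betas
    truth.latent = pd.Series(latent, index=subjects["sample_id"], name="latent")
    return out


# -- orchestration ---------------------------------------------------------


def true_burdens(
    truth: GroundTruth, annotation: AnnotationBundle, config: SyntheticConfig
) -> pd.DataFrame:
    """Burden of the *planted* CNVs (used to generate phenotypes)."""
    calls = truth.cnvs.assign(n_probes=0, caller="truth", confidence=np.nan)
    features = ("spans",) if config.beta_geneset == 0.0 else ("spans", "genesets")
    enc = BurdenEncoder(annotation, features=features, gene_strata=("all",))
    return enc.transform(calls, subjects=truth.subjects["sample_id"])


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from a single seed."""
    annotation = generate_annotation(config)
    truth = generate_truth(annotation, config)
    callsets = generate_callsets(truth, annotation, config)
    qc_metrics = generate_qc_metrics(truth.subjects, config)
    burdens = true_burdens(truth, annotation, config)
    subjects = generate_phenotypes(truth, burdens, config)
    return SyntheticStudy(
        config=config,
        annotation=annotation,
        truth=truth,
        callsets=callsets,
        qc_metrics=qc_metrics,
        subjects=subjects,
    )


def write_fixtures(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write every pipeline input as plain-text fixtures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.annotation.write(outdir / "annotation")
    for caller, g in study.callsets.groupby("caller"):
        io.write_calls(g, outdir / f"calls_{caller}.tsv")
    io.write_table(study.qc_metrics, outdir / "qc_metrics.tsv")
    io.write_table(study.subjects, outdir / "subjects.tsv")
    truth_cnvs = study.truth.cnvs.copy()
    io.write_json(
        {
            "true_betas": study.truth.true_betas,
            "true_cnvs": truth_cnvs.to_dict(orient="records"),
        },
        outdir / "ground_truth.json",
    )
    cfg = asdict(study.config)
    io.write_json(cfg, outdir / "config.json")
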