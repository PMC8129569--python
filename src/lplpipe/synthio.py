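"""Synthetic expression cohorts and immunoglobulin repertoire libraries.

Every downstream stage of the pipeline is exercised against data generated
here, with the planted structure (co-regulated gene clusters, cross-species
signatures, dominant clones) recorded as ground truth.  The expression model
is deliberately simple: per-gene baselines drawn once from a normal law,
class effects as additive log2 shifts, i.i.d. normal noise per cell -- the
log-scale, roughly homoscedastic world the downstream statistics assume.

Repertoire libraries are drawn multinomially: a clonal sample concentrates
probability ``dominant_freq`` on one clonotype shared between its membrane
and secreted libraries (the hallmark of a lymphoplasmacytic clone expressing
both isoforms of the heavy chain), the remainder spread geometrically over
background clones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "ClusterSpec",
    "ExpressionTruth",
    "RepertoireTruth",
    "simulate_expression_cohort",
    "simulate_paired_species",
    "simulate_repertoire",
    "library_id",
]

DEFAULT_EFFECT = 2.0  # log2 units
DEFAULT_NOISE_SD = 0.5
BASELINE_MEAN = 8.0
BASELINE_SD = 1.5
GEOMETRIC_HEAD = 0.05  # rank-abundance head probability of background clones

NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class ClusterSpec:
    """A planted co-regulated gene cluster.

    ``effect`` is the magnitude of the log2 shift applied in the cohort's
    affected class, signed by ``direction``.  ``shifts`` optionally gives an
    explicit class -> signed log2 shift map instead, allowing clusters with
    distinct sample-patterns (without it, same-direction clusters collapse
    to one standardized profile and are unresolvable by clustering).
    """

    size: int
    effect: float
    direction: str = "up"
    shifts: Mapping[str, float] | None = None

    def signed_effect(self) -> float:
        if self.shifts is not None:
            return max(self.shifts.values(), key=abs)
        return self.effect if self.direction == "up" else -self.effect


def _as_cluster_spec(entry) -> ClusterSpec:
    if isinstance(entry, ClusterSpec):
        return entry
    return ClusterSpec(*entry)


@dataclass
class ExpressionTruth:
    """Ground truth for a simulated expression cohort."""

    planted_cluster_of_gene: dict[str, int | None]
    class_of_sample: dict[str, str]
    effect_size_of_cluster: dict[int, float]
    n_true_clusters: int
    human_sign_flipped: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, c in self.planted_cluster_of_gene.items():
            if c is not None and self.effect_size_of_cluster.get(c, 0.0) == 0.0:
                raise ValueError(f"gene {gene} in cluster {c} with zero effect size")

    def cluster_members(self, cluster: int) -> list[str]:
        return [g for g, c in self.planted_cluster_of_gene.items() if c == cluster]

    def to_json(self, path: Path | str) -> None:
        payload = {
            "planted_cluster_of_gene": self.planted_cluster_of_gene,
            "class_of_sample": self.class_of_sample,
            "effect_size_of_cluster": {str(k): v for k, v in self.effect_size_of_cluster.items()},
            "n_true_clusters": self.n_true_clusters,
            "human_sign_flipped": self.human_sign_flipped,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_expression_cohort(
    n_genes: int,
    cluster_spec: Sequence,
    classes: Sequence[tuple[str, int]],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    affected_class: str | None = None,
    species: str = "mouse",
    gene_prefix: str = "G",
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate a log2 expression cohort with planted co-regulated clusters.

    Genes in cluster ``c`` are shifted by that cluster's effect in the
    affected class (default: the second class listed, the "tumor" arm);
    background genes carry no class effect.  Identical seeds give identical
    output.
    """
    specs = [_as_cluster_spec(e) for e in cluster_spec]
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if len(classes) < 2:
        raise ValueError("at least 2 classes are required")
    if any(n < 2 for _, n in classes):
        raise ValueError("every class needs at least 2 samples (variance undefined below)")
    total_planted = sum(s.size for s in specs)
    if total_planted > n_genes:
        raise ValueError(f"cluster sizes sum to {total_planted} > n_genes = {n_genes}")

    labels = [lab for lab, _ in classes]
    if affected_class is None:
        affected_class = labels[1]
    if affected_class not in labels:
        raise ValueError(f"affected_class {affected_class!r} not among classes")

    rng = np.random.default_rng(seed)
    sample_ids = [f"{lab}_{i + 1}" for lab, n in classes for i in range(n)]
    class_of_sample = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    n_samples = len(sample_ids)

    width = max(4, len(str(n_genes)))
    gene_ids = [f"{gene_prefix}{i + 1:0{width}d}" for i in range(n_genes)]

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    planted: dict[str, int | None] = {g: None for g in gene_ids}
    effect_of_cluster: dict[int, float] = {}
    row = 0
    for c, spec in enumerate(specs):
        effect_of_cluster[c] = spec.signed_effect()
        shifts = spec.shifts or {affected_class: spec.signed_effect()}
        for _ in range(spec.size):
            planted[gene_ids[row]] = c
            for j, s in enumerate(sample_ids):
                shift = shifts.get(class_of_sample[s], 0.0)
                values[row, j] += shift
            row += 1

    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    matrix = ExpressionMatrix(df, species, class_of_sample)
    truth = ExpressionTruth(planted, class_of_sample, effect_of_cluster, len(specs))
    return matrix, truth


def _signature_gene_names(signature_size: int, n_background: int) -> tuple[list[str], list[str]]:
    """Mouse (title-case) and human (upper-case) symbol lists, orthologs by case."""
    width = max(4, len(str(signature_size + n_background)))
    mouse = [f"Sig{i + 1:0{width}d}" for i in range(signature_size)]
    mouse += [f"Bkg{i + 1:0{width}d}" for i in range(n_background)]
    human = [g.upper() for g in mouse]
    return mouse, human


def simulate_paired_species(
    signature_size: int,
    discordance_rate: float,
    mouse_classes: Sequence[tuple[str, int]],
    human_classes: Sequence[tuple[str, int]],
    effect: float = DEFAULT_EFFECT,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    n_background: int = 0,
    mouse_affected_class: str | None = None,
    human_positive_class: str | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionTruth]:
    """Simulate a mouse cohort and a human cohort sharing a planted signature.

    Signature genes alternate up/down and carry class effects of the same
    sign in both species, except a Bernoulli(``discordance_rate``) fraction
    whose human sign is flipped.  In the human cohort only the designated
    positive class (default: the second class listed) carries the signature;
    the remaining classes are signature-silent, so the cohort may contain
    any number of entities.  Ortholog pairing follows the symbol convention
    mouse title-case <-> human upper-case.
    """
    if signature_size <= 0:
        raise ValueError("signature_size must be positive")
    if not 0.0 <= discordance_rate <= 1.0:
        raise ValueError("discordance_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    mouse_genes, human_genes = _signature_gene_names(signature_size, n_background)
    directions = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(signature_size)])
    flipped = rng.random(signature_size) < discordance_rate

    mouse, _ = _species_cohort(
        mouse_genes, signature_size, directions * effect, mouse_classes,
        mouse_affected_class, noise_sd, rng, "mouse",
    )
    human_dirs = directions * np.where(flipped, -1.0, 1.0)
    if human_positive_class is None:
        human_positive_class = human_classes[1][0]
    human, _ = _species_cohort(
        human_genes, signature_size, human_dirs * effect, human_classes,
        human_positive_class, noise_sd, rng, "human",
    )

    planted = {g: (0 if directions[i] > 0 else 1) for i, g in enumerate(mouse_genes[:signature_size])}
    planted.update({g: None for g in mouse_genes[signature_size:]})
    class_of_sample = {f"mouse:{s}": c for s, c in mouse.class_of_sample.items()}
    class_of_sample.update({f"human:{s}": c for s, c in human.class_of_sample.items()})
    truth = ExpressionTruth(
        planted,
        class_of_sample,
        {0: effect, 1: -effect},
        2,
        human_sign_flipped={
            g: bool(flipped[i]) for i, g in enumerate(mouse_genes[:signature_size])
        },
    )
    return mouse, human, truth


def _species_cohort(
    gene_ids: list[str],
    signature_size: int,
    signed_effects: np.ndarray,
    classes: Sequence[tuple[str, int]],
    affected_class: str | None,
    noise_sd: float,
    rng: np.random.Generator,
    species: str,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    labels = [lab for lab, _ in classes]
    if affected_class is None:
        affected_class = labels[1]
    if affected_class not in labels:
        raise ValueError(f"affected class {affected_class!r} not among {labels}")
    sample_ids = [f"{lab}_{i + 1}" for lab, n in classes for i in range(n)]
    class_of_sample = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    n_genes, n_samples = len(gene_ids), len(sample_ids)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    in_class = np.array([class_of_sample[s] == affected_class for s in sample_ids])
    values[:signature_size, in_class] += signed_effects[:, None]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(df, species, class_of_sample), class_of_sample


# ---------------------------------------------------------------------------
# Repertoire simulation
# ---------------------------------------------------------------------------

ISOFORMS = ("membrane", "secreted")
BARCODE_LEN = 8
LEADER_LEN = 40
JUNCTION_LEN = 36
PRIMER_LEN = 20
READ_LEN = 60


def library_id(sample: str, chain: str, isoform: str) -> str:
    return f"{sample}|{chain}|{isoform}"


@dataclass
class RepertoireTruth:
    """Planted clonality structure of a simulated repertoire run."""

    dominant_freq_of_library: dict[str, float]
    dominant_key_of_sample: dict[str, tuple[str, str, str]]
    is_clonal: dict[str, bool]

    def __post_init__(self) -> None:
        for lib, f in self.dominant_freq_of_library.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"dominant frequency of {lib} outside [0, 1]")

    def to_json(self, path: Path | str) -> None:
        payload = {
            "dominant_freq_of_library": self.dominant_freq_of_library,
            "dominant_key_of_sample": {k: list(v) for k, v in self.dominant_key_of_sample.items()},
            "is_clonal": self.is_clonal,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=length)])


def _geometric_probs(n: int, head: float) -> np.ndarray:
    p = head * (1.0 - head) ** np.arange(n)
    return p / p.sum()


def _distinct_seqs(rng: np.random.Generator, n: int, length: int, min_dist: int) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, s)) >= min_dist for s in out):
            out.append(cand)
    return out


def simulate_repertoire(
    samples: Sequence[tuple[str, bool, float]],
    n_background_clones: int = 200,
    n_reads: int = 10_000,
    chains: Iterable[str] = ("mu", "gamma"),
    seed: int = 0,
    head_prob: float = GEOMETRIC_HEAD,
    clonal_chains: Iterable[str] = ("mu",),
    fastq_dir: Path | str | None = None,
) -> tuple[pd.DataFrame, RepertoireTruth]:
    """Simulate clonal/polyclonal 5'RACE libraries as an AIRR-style table.

    Each (sample, chain) yields a membrane and a secreted library of
    ``n_reads`` reads.  Clonal samples (in ``clonal_chains``) put probability
    ``dominant_freq`` on one clonotype shared by both isoform libraries --
    the same V(D)J rearrangement expressed as surface and secreted heavy
    chain -- with the remainder spread geometrically over background clones
    whose rank order is shuffled independently per library.  With
    ``fastq_dir`` set, overlapping read pairs plus barcode/primer tables are
    emitted so the read-level pipeline can reconstruct the table.
    """
    chains = list(chains)
    if n_reads < 100:
        raise ValueError("n_reads must be at least 100")
    for sample, is_clonal, freq in samples:
        if is_clonal and not 0.0 < freq < 1.0:
            raise ValueError(f"dominant_freq of clonal sample {sample} must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    clonal_chains = set(clonal_chains)
    v_pool = [f"IGHV{i + 1}-{j + 1}" for i in range(8) for j in range(3)]
    j_pool = [f"IGHJ{i + 1}" for i in range(4)]

    rows: list[dict] = []
    reads: list[tuple[str, str]] = []  # (template, read id prefix) for FASTQ
    dominant_freq_of_library: dict[str, float] = {}
    dominant_key_of_sample: dict[str, tuple[str, str, str]] = {}
    is_clonal_map: dict[str, bool] = {}

    barcodes = _distinct_seqs(rng, len(samples), BARCODE_LEN, 3)
    barcode_of_sample = {s[0]: bc for s, bc in zip(samples, barcodes)}
    primers = _distinct_seqs(rng, len(chains) * len(ISOFORMS), PRIMER_LEN, 5)
    primer_of_lib = {
        (chain, iso): primers[i]
        for i, (chain, iso) in enumerate((c, f) for c in chains for f in ISOFORMS)
    }

    for sample, is_clonal, freq in samples:
        is_clonal_map[sample] = bool(is_clonal)
        dom = None
        if is_clonal:
            dom = (
                str(rng.choice(v_pool)),
                str(rng.choice(j_pool)),
                _random_seq(rng, JUNCTION_LEN),
            )
            dominant_key_of_sample[sample] = dom
        dom_leader = _random_seq(rng, LEADER_LEN)
        for chain in chains:
            # Background clone identities shared between the two isoform
            # libraries of a (sample, chain); abundance ranks are not.
            bg = [
                (
                    str(rng.choice(v_pool)),
                    str(rng.choice(j_pool)),
                    _random_seq(rng, JUNCTION_LEN),
                    _random_seq(rng, LEADER_LEN),
                )
                for _ in range(n_background_clones)
            ]
            geom = _geometric_probs(n_background_clones, head_prob)
            clonal_here = is_clonal and chain in clonal_chains
            for isoform in ISOFORMS:
                lib = library_id(sample, chain, isoform)
                perm = rng.permutation(n_background_clones)
                bg_probs = geom[perm]
                if clonal_here:
                    probs = np.concatenate([[freq], (1.0 - freq) * bg_probs])
                    clones = [(*dom, dom_leader)] + bg
                    dominant_freq_of_library[lib] = freq
                else:
                    probs = bg_probs
                    clones = bg
                counts = rng.multinomial(n_reads, probs)
                for idx in np.nonzero(counts)[0]:
                    v, j, junction, leader = clones[idx]
                    rows.append(
                        {
                            "sequence_id": f"{lib}|c{idx}",
                            "v_call": v,
                            "j_call": j,
                            "junction": junction,
                            "duplicate_count": int(counts[idx]),
                            "sample_id": sample,
                            "chain": chain,
                            "isoform": isoform,
                        }
                    )
                    if fastq_dir is not None:
                        template = (
                            barcode_of_sample[sample]
                            + leader
                            + junction
                            + primer_of_lib[(chain, isoform)]
                        )
                        for r in range(int(counts[idx])):
                            reads.append((template, f"{lib}|c{idx}|r{r}"))

    table = pd.DataFrame(rows)
    truth = RepertoireTruth(dominant_freq_of_library, dominant_key_of_sample, is_clonal_map)
    if fastq_dir is not None:
        _emit_fastq(Path(fastq_dir), reads, barcode_of_sample, primer_of_lib)
    return table, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _emit_fastq(
    out: Path,
    reads: list[tuple[str, str]],
    barcode_of_sample: dict[str, str],
    primer_of_lib: dict[tuple[str, str], str],
) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out.mkdir(parents=True, exist_ok=True)
    r1, r2 = [], []
    for template, rid in reads:
        fwd = template[:READ_LEN]
        rev = _revcomp(template[-READ_LEN:])
        for records, seq in ((r1, fwd), (r2, rev)):
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
    seqio_write(r1, out / "reads_R1.fastq", "fastq")
    seqio_write(r2, out / "reads_R2.fastq", "fastq")
    pd.DataFrame(
        {"barcode": list(barcode_of_sample.values()), "sample_id": list(barcode_of_sample)}
    ).to_csv(out / "barcodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"primer": p, "chain": chain, "isoform": iso}
            for (chain, iso), p in primer_of_lib.items()
        ]
    ).to_csv(out / "primers.tsv", sep="\t", index=False)
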