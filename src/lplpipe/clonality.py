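"""Isoform-resolved immunoglobulin heavy-chain clonality.

5'RACE amplicons anchored at membrane- or secreted-exon primers let the
same V(D)J rearrangement be observed as surface-bound and secreted heavy
chain mRNA.  This module merges overlapping read pairs, demultiplexes them
by sample barcode and isoform primer, aggregates clonotypes (V gene, J
gene, junction -- or exact trimmed sequence as a fallback), reports the
top-N clone frequencies per library, matches the dominant membrane vs
secreted clones, and compares dominant-clone abundance between groups with
an exact Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MergedRead",
    "CloneReport",
    "merge_read_pair",
    "read_fastq_pairs",
    "demultiplex",
    "build_clonotypes",
    "top_clone_frequencies",
    "dominant_isoform_match",
    "ranksum_exact",
]

log = logging.getLogger(__name__)

AIRR_COLUMNS = ("v_call", "j_call", "junction", "duplicate_count")
JUNCTION_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Read merging
# ---------------------------------------------------------------------------


@dataclass
class MergedRead:
    sequence: str
    quality: list[int]
    sample_id: str | None = None
    chain: str | None = None
    isoform: str | None = None
    trimmed: str | None = None  # barcode/primer-trimmed sequence (fallback key)


def merge_read_pair(
    read1: tuple[str, Sequence[int]],
    read2: tuple[str, Sequence[int]],
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> MergedRead | None:
    """Merge a forward/reverse read pair by their 3' overlap.

    ``read2`` is reverse-complemented, overlaps are scanned from the
    longest down to ``min_overlap``, overlaps with mismatch fraction at
    most ``max_mismatch_density`` are accepted, and among accepted overlaps
    the one with lowest mismatch density wins (ties -> longest).  In the
    overlap the base with the higher quality score is kept.  Returns None
    when no overlap qualifies.
    """
    s1, q1 = read1[0].upper(), list(read1[1])
    s2, q2 = read2[0].upper(), list(read2[1])
    if not s1 or not s2:
        raise ValueError("empty read")
    rc2 = _revcomp(s2)
    rq2 = q2[::-1]

    best: tuple[float, int] | None = None  # (density, overlap length)
    for olen in range(min(len(s1), len(rc2)), min_overlap - 1, -1):
        tail = s1[len(s1) - olen :]
        head = rc2[:olen]
        mism = sum(a != b for a, b in zip(tail, head))
        density = mism / olen
        if density <= max_mismatch_density:
            if best is None or density < best[0]:
                best = (density, olen)
    if best is None:
        return None
    olen = best[1]
    off = len(s1) - olen
    seq = list(s1[:off])
    qual = q1[:off]
    for i in range(olen):
        b1, b2 = s1[off + i], rc2[i]
        c1, c2 = q1[off + i], rq2[i]
        if b1 == b2:
            seq.append(b1)
            qual.append(max(c1, c2))
        elif c1 >= c2:
            seq.append(b1)
            qual.append(c1)
        else:
            seq.append(b2)
            qual.append(c2)
    seq.extend(rc2[olen:])
    qual.extend(rq2[olen:])
    return MergedRead("".join(seq), qual)


def read_fastq_pairs(r1_path: Path | str, r2_path: Path | str):
    """Yield ((seq, qual), (seq, qual)) pairs from two FASTQ files."""
    from Bio import SeqIO

    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        yield (
            (str(rec1.seq), rec1.letter_annotations["phred_quality"]),
            (str(rec2.seq), rec2.letter_annotations["phred_quality"]),
        )


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    merged: Iterable[MergedRead],
    barcode_table: Mapping[str, str],
    primer_table: Mapping[str, tuple[str, str]],
) -> tuple[list[MergedRead], dict[str, int]]:
    """Annotate merged reads with (sample, chain, isoform).

    The barcode is matched exactly at the 5' end; the isoform primer with
    at most 1 mismatch at the 3' end.  Unassigned reads are dropped and
    tallied.  Colliding barcodes raise.
    """
    if len(set(barcode_table)) != len(barcode_table):
        raise ValueError("colliding barcodes in table")
    bc_len = {len(b) for b in barcode_table}
    pr_len = {len(p) for p in primer_table}
    if len(bc_len) != 1 or len(pr_len) != 1:
        raise ValueError("barcodes (and primers) must share a common length")
    bl, pl = bc_len.pop(), pr_len.pop()

    out: list[MergedRead] = []
    tally = {"assigned": 0, "no_barcode": 0, "no_primer": 0}
    for read in merged:
        sample = barcode_table.get(read.sequence[:bl])
        if sample is None:
            tally["no_barcode"] += 1
            continue
        tail = read.sequence[-pl:]
        best_primer, best_d = None, pl + 1
        for primer in primer_table:
            d = _hamming(tail, primer)
            if d < best_d:
                best_primer, best_d = primer, d
        if best_primer is None or best_d > 1:
            tally["no_primer"] += 1
            continue
        chain, isoform = primer_table[best_primer]
        out.append(
            MergedRead(
                sequence=read.sequence,
                quality=read.quality,
                sample_id=sample,
                chain=chain,
                isoform=isoform,
                trimmed=read.sequence[bl : len(read.sequence) - pl],
            )
        )
        tally["assigned"] += 1
    log.info("demultiplex: %s", tally)
    return out, tally


def load_barcode_table(path: Path | str) -> dict[str, str]:
    """Load a barcode -> sample TSV, rejecting colliding barcodes."""
    df = pd.read_csv(path, sep="\t")
    if df["barcode"].duplicated().any():
        raise ValueError("colliding barcodes in table")
    return dict(zip(df["barcode"], df["sample_id"]))


def load_primer_table(path: Path | str) -> dict[str, tuple[str, str]]:
    """Load a primer -> (chain, isoform) TSV, rejecting colliding primers."""
    df = pd.read_csv(path, sep="\t")
    if df["primer"].duplicated().any():
        raise ValueError("colliding primers in table")
    return {r.primer: (r.chain, r.isoform) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Clonotype tables
# ---------------------------------------------------------------------------


def build_clonotypes(
    records: pd.DataFrame | Sequence[MergedRead],
) -> pd.DataFrame:
    """Aggregate annotated records into a clonotype table.

    AIRR input (a DataFrame) keys clonotypes by (v_call, j_call, junction);
    demultiplexed reads fall back to exact identity of the trimmed merged
    sequence.  Counts are summed within each (sample, chain, isoform)
    library.
    """
    if isinstance(records, pd.DataFrame):
        required = list(AIRR_COLUMNS) + ["sample_id", "chain", "isoform"]
        missing = [c for c in required if c not in records.columns]
        if missing:
            raise ValueError(f"AIRR table missing required columns: {missing}")
        bad = [
            i
            for i, junc in enumerate(records["junction"].astype(str))
            if not junc or not set(junc) <= JUNCTION_ALPHABET
        ]
        if bad:
            raise ValueError(f"invalid junction alphabet at row(s) {bad[:5]}")
        grouped = (
            records.groupby(
                ["sample_id", "chain", "isoform", "v_call", "j_call", "junction"],
                as_index=False,
            )["duplicate_count"]
            .sum()
            .rename(columns={"duplicate_count": "count"})
        )
        return grouped.sort_values(
            ["sample_id", "chain", "isoform", "v_call", "j_call", "junction"]
        ).reset_index(drop=True)

    rows = []
    for read in records:
        if read.sample_id is None or read.trimmed is None:
            raise ValueError("build_clonotypes needs demultiplexed reads")
        rows.append(
            {
                "sample_id": read.sample_id,
                "chain": read.chain,
                "isoform": read.isoform,
                "v_call": "",
                "j_call": "",
                "junction": read.trimmed,
                "duplicate_count": 1,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "chain", "isoform", "v_call", "j_call", "junction", "count"]
        )
    return build_clonotypes(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Clone reports
# ---------------------------------------------------------------------------


@dataclass
class CloneReport:
    """Per-library top-N clone frequencies and dominant-clone matching."""

    n_top: int
    libraries: dict[tuple[str, str, str], dict] = field(default_factory=dict)

    def top_clones(self, sample: str, chain: str, isoform: str) -> list[tuple[tuple, float]]:
        return self.libraries[(sample, chain, isoform)]["top_clones"]

    def dominant_key(self, sample: str, chain: str, isoform: str) -> tuple:
        return self.libraries[(sample, chain, isoform)]["dominant_key"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sample, chain, isoform), lib in sorted(self.libraries.items()):
            for rank, (key, freq) in enumerate(lib["top_clones"], start=1):
                rows.append(
                    {
                        "sample_id": sample,
                        "chain": chain,
                        "isoform": isoform,
                        "rank": rank,
                        "v_call": key[0],
                        "j_call": key[1],
                        "junction": key[2],
                        "count": lib["counts"][key],
                        "frequency": freq,
                    }
                )
        return pd.DataFrame(rows)


def top_clone_frequencies(table: pd.DataFrame, n_top: int = 5) -> CloneReport:
    """Per-library relative clone frequencies, truncated to the top N.

    Frequencies are count/total within each (sample, chain, isoform)
    library; ordering is by descending frequency with lexicographic key as
    the tie-break; the dominant clone is the first entry.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if "count" not in table.columns and "duplicate_count" in table.columns:
        table = build_clonotypes(table)  # raw AIRR rows: aggregate first
    report = CloneReport(n_top=n_top)
    if table.empty:
        log.warning("top_clone_frequencies: empty clonotype table")
        return report
    for (sample, chain, isoform), grp in table.groupby(["sample_id", "chain", "isoform"]):
        total = int(grp["count"].sum())
        if total == 0:
            log.warning("library %s|%s|%s empty; omitted", sample, chain, isoform)
            continue
        keyed = {
            (r.v_call, r.j_call, r.junction): int(r.count)
            for r in grp.itertuples(index=False)
        }
        ordered = sorted(keyed.items(), key=lambda kv: (-kv[1], kv[0]))
        top = [(key, cnt / total) for key, cnt in ordered[:n_top]]
        report.libraries[(sample, chain, isoform)] = {
            "total_reads": total,
            "counts": keyed,
            "top_clones": top,
            "dominant_key": top[0][0],
        }
    return report


def dominant_isoform_match(report: CloneReport, sample: str, chain: str) -> bool:
    """True iff the dominant membrane and secreted clonotype keys agree."""
    try:
        mem = report.dominant_key(sample, chain, "membrane")
        sec = report.dominant_key(sample, chain, "secreted")
    except KeyError as exc:
        raise KeyError(f"missing isoform library for ({sample}, {chain})") from exc
    return mem == sec


# ---------------------------------------------------------------------------
# Exact rank-sum test
# ---------------------------------------------------------------------------

EXACT_LIMIT = 12


def ranksum_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon rank-sum p-value by exhaustive enumeration of mid-rank
    assignments (n + m <= 12); larger samples use the normal approximation
    with tie correction and continuity correction.

    ``alternative='less'`` tests whether x tends to be smaller than y.
    """
    x, y = list(map(float, x)), list(map(float, y))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty group")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.array(x + y)
    ranks = sps.rankdata(pooled)  # mid-ranks
    w_obs = ranks[:n].sum()

    total = n + m
    if total <= EXACT_LIMIT:
        sums = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(total), n)]
        )
        eps = 1e-9
        p_less = float((sums <= w_obs + eps).mean())
        p_greater = float((sums >= w_obs - eps).mean())
    else:
        log.info("ranksum_exact: n+m=%d > %d, normal approximation", total, EXACT_LIMIT)
        mean = n * (total + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
        if var <= 0:
            return 1.0
        sd = math.sqrt(var)
        p_less = float(sps.norm.cdf((w_obs - mean + 0.5) / sd))
        p_greater = float(sps.norm.sf((w_obs - mean - 0.5) / sd))

    if alternative == "less":
        return min(1.0, p_less)
    if alternative == "greater":
        return min(1.0, p_greater)
    return min(1.0, 2.0 * min(p_less, p_greater))
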