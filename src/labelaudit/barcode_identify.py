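"""Per-sample species assignment from paired Sanger COI reads and hit tables.

The pipeline: quality-trim each read (front trim, 3' sliding-window cut,
length cap), reverse-complement the reverse read, align the pair globally,
call a quality-weighted consensus, then curate the reference-database hit
table (coverage/identity/e-value thresholds plus two confidence rules: a
species' hits must represent at least 1% of its database entries, and
single-entry species are dropped) and assign the best-supported species.

Assignment failure is a first-class outcome with a reason code:
``no_amplification`` (no reads), ``low_quality`` (both reads rejected by
trimming), ``no_hits``, ``low_confidence`` (hits existed but none survived
curation), or ``contamination_excluded`` (best hit is a declared
co-ingredient of a mixed product, e.g. pig in a pork-and-prawn dumpling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrimConfig",
    "FilterConfig",
    "ConsensusSequence",
    "SpeciesCall",
    "trim_read",
    "reverse_complement",
    "align_pair",
    "call_consensus",
    "filter_hits",
    "assign_species",
    "identify_sample",
    "identify_cohort",
    "read_fastq",
]

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")
GAP = "-"


@dataclass(frozen=True)
class TrimConfig:
    """Quality-trimming parameters (Phred scale).

    Defaults follow common Sanger-cleanup practice for COI barcodes:
    quality floor 20, 30 bases cut from the front (primer region), reads
    capped at 250 bases, 10-base 3' cutting window, and a 100-base minimum
    retained length.
    """

    qual_floor: int = 20
    front_trim: int = 30
    max_len: int = 250
    window: int = 10
    min_len: int = 100

    def __post_init__(self):
        if min(self.qual_floor, self.front_trim, self.max_len, self.window, self.min_len) <= 0:
            raise ValueError("all trim parameters must be positive")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


@dataclass(frozen=True)
class FilterConfig:
    """Hit-curation thresholds.

    ``min_entry_fraction`` is the minimum share of a species' total database
    entries that must appear among the hits (guards against one spurious
    match to a heavily represented species); ``drop_single_entry_species``
    removes species whose entire database presence is a single record.
    Identity/coverage cuts are inclusive (>= 98).
    """

    min_coverage: float = 98.0
    min_identity: float = 98.0
    max_evalue: float = 1e-10
    min_entry_fraction: float = 0.01
    drop_single_entry_species: bool = True
    drop_supraspecific: bool = True

    def __post_init__(self):
        if not (0 <= self.min_coverage <= 100 and 0 <= self.min_identity <= 100):
            raise ValueError("coverage/identity thresholds must be percentages")
        if self.max_evalue <= 0 or not 0 <= self.min_entry_fraction <= 1:
            raise ValueError("invalid max_evalue or min_entry_fraction")


@dataclass
class ConsensusSequence:
    sample_id: str
    seq: str
    per_base_source: list[str]  # "agreed" | "forward" | "reverse"
    pair_disagreements: int


@dataclass
class SpeciesCall:
    sample_id: str
    status: str  # assigned|no_amplification|low_quality|no_hits|low_confidence|contamination_excluded
    species: str | None = None
    supporting_hits: int = 0
    ambiguous: bool = False

    def __post_init__(self):
        assert (self.species is not None) == (self.status == "assigned")


# --------------------------------------------------------------------------
# read preparation
# --------------------------------------------------------------------------


def trim_read(seq: str, qual: list[int], cfg: TrimConfig = TrimConfig()):
    """Trim one read; returns ``(seq, qual)`` or ``None`` when rejected.

    Order of operations: remove ``front_trim`` bases from the 5' end; from
    the 3' end repeatedly drop the trailing window while its mean quality is
    below ``qual_floor``; cap at ``max_len``.  The read is rejected if the
    retained length is below ``min_len`` or its mean quality is below
    ``qual_floor``.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence and quality lengths differ")
    s = seq[cfg.front_trim:]
    q = list(qual[cfg.front_trim:])
    while s:
        w = min(cfg.window, len(s))
        if float(np.mean(q[-w:])) < cfg.qual_floor:
            s, q = s[:-w], q[:-w]
        else:
            break
    s, q = s[: cfg.max_len], q[: cfg.max_len]
    if len(s) < cfg.min_len or float(np.mean(q)) < cfg.qual_floor:
        return None
    return s, q


def reverse_complement(seq: str, qual: list[int] | None = None):
    """Reverse-complement a sequence, reversing its qualities in step."""
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    rc = seq.upper().translate(_COMP)[::-1]
    if qual is None:
        return rc
    return rc, list(qual)[::-1]


# --------------------------------------------------------------------------
# pairwise alignment and consensus
# --------------------------------------------------------------------------

MATCH, MISMATCH, GAP_PENALTY = 1, -1, -2


def align_pair(a: str, b: str) -> tuple[str, str, int]:
    """Optimal Needleman-Wunsch global alignment of two reads.

    Scoring: match +1, mismatch -1, gap -2.  Ties in the traceback prefer
    diagonal over up (gap in ``b``) over left (gap in ``a``), making the
    output deterministic.  Returns ``(aligned_a, aligned_b, score)``.
    """
    if not a or not b:
        raise ValueError("align_pair requires two non-empty sequences")
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype="S1")
    bv = np.frombuffer(b.encode(), dtype="S1")
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=diag 1=up 2=left
    score[0, :] = GAP_PENALTY * np.arange(m + 1)
    score[:, 0] = GAP_PENALTY * np.arange(n + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], MATCH, MISMATCH)
        diag = score[i - 1, :-1] + sub
        up_col = score[i - 1, 1:] + GAP_PENALTY
        row = score[i]
        prev = score[i - 1]
        # left dependency is sequential within the row
        acc = row  # alias
        acc[0] = GAP_PENALTY * i
        d = diag
        u = up_col
        for j in range(1, m + 1):
            left = acc[j - 1] + GAP_PENALTY
            best = d[j - 1]
            p = 0
            if u[j - 1] > best:
                best = u[j - 1]
                p = 1
            if left > best:
                best = left
                p = 2
            acc[j] = best
            ptr[i, j] = p
    i, j = n, m
    ra, rb = [], []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and (p == 1 or j == 0):
            ra.append(a[i - 1])
            rb.append(GAP)
            i -= 1
        else:
            ra.append(GAP)
            rb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), int(score[n, m])


def call_consensus(
    aligned_fwd: str,
    aligned_rev: str,
    fwd_qual: list[int],
    rev_qual: list[int],
    sample_id: str = "",
    tie_base: str = "N",
) -> ConsensusSequence:
    """Quality-weighted consensus of an aligned read pair.

    Agreeing columns emit the shared base.  Disagreeing base-vs-base
    columns emit the base with the higher Phred quality (quality ties emit
    ``tie_base``).  Gap columns emit the non-gap base regardless of quality.
    The consensus never contains gap characters.
    """
    if len(aligned_fwd) != len(aligned_rev):
        raise ValueError("aligned strings differ in length")
    fi = ri = 0
    seq, src = [], []
    disagreements = 0
    for cf, cr in zip(aligned_fwd, aligned_rev):
        if cf != GAP and cr != GAP:
            qf, qr = fwd_qual[fi], rev_qual[ri]
            fi += 1
            ri += 1
            if cf == cr:
                seq.append(cf)
                src.append("agreed")
            else:
                disagreements += 1
                if qf > qr:
                    seq.append(cf)
                    src.append("forward")
                elif qr > qf:
                    seq.append(cr)
                    src.append("reverse")
                else:
                    seq.append(tie_base)
                    src.append("agreed")
        elif cf != GAP:
            fi += 1
            seq.append(cf)
            src.append("forward")
        else:
            ri += 1
            seq.append(cr)
            src.append("reverse")
    return ConsensusSequence(sample_id, "".join(seq), src, disagreements)


# --------------------------------------------------------------------------
# hit curation and assignment
# --------------------------------------------------------------------------

_HIT_COLS = ["qseqid", "species", "db", "identity", "coverage", "evalue", "species_db_entries"]


def filter_hits(hits: pd.DataFrame, cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Curate a hit table; order-independent and idempotent.

    Threshold filters (coverage, identity, e-value, species-rank) run
    first; support counts per (query, species) are then computed on the
    surviving rows, and the entry-fraction and single-entry rules remove
    whole species groups.  The output carries a ``hits_for_species`` column.
    """
    missing = [c for c in _HIT_COLS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    bad = hits.index[hits["species_db_entries"].isna()]
    if len(bad):
        raise ValueError(f"species_db_entries missing at rows {list(bad[:5])}")
    h = hits.copy()
    keep = (
        (h["coverage"] >= cfg.min_coverage)
        & (h["identity"] >= cfg.min_identity)
        & (h["evalue"] <= cfg.max_evalue)
    )
    if cfg.drop_supraspecific:
        # species-rank entries are two-token Latin binomials; reject
        # "Genus sp.", single tokens, and free-text descriptions
        toks = h["species"].astype(str).str.strip().str.split()
        keep &= toks.map(
            lambda t: len(t) == 2 and not t[1].rstrip(".").lower() in {"sp", "spp", "cf", "aff"}
        )
    h = h[keep].copy()
    support = h.groupby(["qseqid", "species"])["species"].transform("size")
    h["hits_for_species"] = support.astype(int) if len(h) else pd.Series(dtype=int)
    if len(h):
        frac_ok = h["hits_for_species"] / h["species_db_entries"] >= cfg.min_entry_fraction
        h = h[frac_ok]
        if cfg.drop_single_entry_species:
            h = h[h["species_db_entries"] > 1]
    return h.reset_index(drop=True)


def assign_species(
    filtered: pd.DataFrame,
    sample_id: str = "",
    exclusion_list: set[str] | frozenset[str] = frozenset(),
    had_raw_hits: bool = True,
) -> SpeciesCall:
    """Pick the assigned species from curated hits.

    Species are ranked by (max identity, max coverage, hits_for_species)
    descending with an alphabetical tie-break; a tie on all three keys sets
    the ``ambiguous`` flag.  An empty curated table yields ``no_hits`` (or
    ``low_confidence`` when raw hits existed); a winner on the product's
    co-ingredient ``exclusion_list`` yields ``contamination_excluded``.
    """
    if filtered.empty:
        status = "low_confidence" if had_raw_hits else "no_hits"
        return SpeciesCall(sample_id, status)
    excl = {str(s).lower() for s in exclusion_list}
    agg = (
        filtered.groupby("species")
        .agg(
            identity=("identity", "max"),
            coverage=("coverage", "max"),
            support=("hits_for_species", "max"),
        )
        .reset_index()
    )
    agg = agg.sort_values(
        ["identity", "coverage", "support", "species"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best = agg.iloc[0]
    if str(best["species"]).lower() in excl:
        return SpeciesCall(sample_id, "contamination_excluded")
    ambiguous = len(agg) > 1 and bool(
        (agg.iloc[1][["identity", "coverage", "support"]] == best[["identity", "coverage", "support"]]).all()
    )
    return SpeciesCall(
        sample_id,
        "assigned",
        species=str(best["species"]),
        supporting_hits=int(best["support"]),
        ambiguous=ambiguous,
    )


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def identify_sample(
    sample_id: str,
    pair: dict | None,
    hits: pd.DataFrame | None,
    trim_cfg: TrimConfig = TrimConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
    exclusion_list: frozenset[str] = frozenset(),
) -> tuple[SpeciesCall, ConsensusSequence | None]:
    """Run one sample through trimming, consensus, curation and assignment.

    ``pair`` holds forward/reverse sequence and quality; ``None`` means no
    reads (failed amplification).  ``hits`` is the sample's reference hit
    table (already restricted to this query).
    """
    if pair is None:
        return SpeciesCall(sample_id, "no_amplification"), None
    fwd = trim_read(pair["forward_seq"], pair["forward_qual"], trim_cfg)
    rev = trim_read(pair["reverse_seq"], pair["reverse_qual"], trim_cfg)
    if fwd is None and rev is None:
        return SpeciesCall(sample_id, "low_quality"), None
    if fwd is not None and rev is not None:
        rseq, rqual = reverse_complement(rev[0], rev[1])
        af, ar, _ = align_pair(fwd[0], rseq)
        cons = call_consensus(af, ar, fwd[1], rqual, sample_id)
    else:
        s, q = fwd if fwd is not None else reverse_complement(rev[0], rev[1])
        cons = ConsensusSequence(sample_id, s, ["forward" if fwd else "reverse"] * len(s), 0)
    if hits is None or hits.empty:
        return SpeciesCall(sample_id, "no_hits"), cons
    surviving = filter_hits(hits, filter_cfg)
    call = assign_species(surviving, sample_id, exclusion_list, had_raw_hits=True)
    return call, cons


def identify_cohort(
    reads: dict[str, dict | None],
    hit_table: pd.DataFrame,
    trim_cfg: TrimConfig = TrimConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
    exclusions: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Species-call table for a cohort; deterministic in its inputs."""
    exclusions = exclusions or {}
    by_query = dict(tuple(hit_table.groupby("qseqid"))) if len(hit_table) else {}
    rows = []
    for sid in sorted(reads):
        call, cons = identify_sample(
            sid,
            reads[sid],
            by_query.get(sid),
            trim_cfg,
            filter_cfg,
            exclusions.get(sid, frozenset()),
        )
        rows.append(
            {
                "sample_id": sid,
                "status": call.status,
                "species": call.species,
                "supporting_hits": call.supporting_hits,
                "ambiguous": call.ambiguous,
                "consensus_len": len(cons.seq) if cons else 0,
                "pair_disagreements": cons.pair_disagreements if cons else 0,
            }
        )
    return pd.DataFrame(rows)


def consensus_cohort(
    reads: dict[str, dict | None], trim_cfg: TrimConfig = TrimConfig()
) -> dict[str, str]:
    """Consensus sequence per sample (samples failing QC are omitted).

    Convenience for driving reference-database search: the same trimming,
    alignment and consensus logic as :func:`identify_sample`.
    """
    out = {}
    for sid in sorted(reads):
        pair = reads[sid]
        if pair is None:
            continue
        fwd = trim_read(pair["forward_seq"], pair["forward_qual"], trim_cfg)
        rev = trim_read(pair["reverse_seq"], pair["reverse_qual"], trim_cfg)
        if fwd is None and rev is None:
            continue
        if fwd is not None and rev is not None:
            rseq, rqual = reverse_complement(rev[0], rev[1])
            af, ar, _ = align_pair(fwd[0], rseq)
            out[sid] = call_consensus(af, ar, fwd[1], rqual, sid).seq
        else:
            s, _q = fwd if fwd is not None else reverse_complement(rev[0], rev[1])
            out[sid] = s
    return out


def read_fastq(path) -> dict[str, tuple[str, list[int]]]:
    """Minimal Phred+33 FASTQ reader returning {id: (seq, qual)}."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        out[rec.id] = (str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
    return out
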