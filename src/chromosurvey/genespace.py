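"""Conserved gene-space reconstruction.

The low-copy read/contig set is compared against reference proteomes
(Brachypodium, rice, sorghum, barley) and wheat UniGene/UniProt
collections. Matches are filtered per reference set, restricted to
reciprocal best hits for protein queries, purged of redundant singletons
(an amplification-bias guard), and partitioned into conserved versus
non-conserved gene-associated sequences. Protein-anchored gene models are
then assembled by merging mapped segments on each reference CDS with 'n'
gap fill, and the genic fraction of the chromosome is extrapolated to a
genome-wide gene-count estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .seqio import HomologyMatch

#: reference-set precedence used when one sequence matches several proteomes
PROTEOME_PRECEDENCE = ("brachypodium", "rice", "sorghum", "barley")
PROTEOME_SETS = frozenset(PROTEOME_PRECEDENCE)
NONCONSERVED_SETS = frozenset({"unigene", "uniprot"})


@dataclass
class FilterProfile:
    """Per-reference-set retention thresholds (all inclusive)."""

    reference_set: str
    evalue_max: float
    min_align_len: int
    min_ppos: float | None = None
    min_pident: float | None = None
    requires_rbh: bool = False

    def __post_init__(self) -> None:
        if (self.min_ppos is None) == (self.min_pident is None):
            raise ValueError("exactly one of min_ppos/min_pident must be set")
        if self.evalue_max <= 0 or self.min_align_len <= 0:
            raise ValueError("thresholds must be positive")


#: the survey's per-reference filtering profiles
DEFAULT_PROFILES: dict[str, FilterProfile] = {
    "brachypodium": FilterProfile("brachypodium", 1e-6, 30, min_ppos=75.0, requires_rbh=True),
    "rice": FilterProfile("rice", 1e-6, 30, min_ppos=75.0, requires_rbh=True),
    "sorghum": FilterProfile("sorghum", 1e-6, 30, min_ppos=75.0, requires_rbh=True),
    "barley": FilterProfile("barley", 1e-6, 30, min_ppos=90.0, requires_rbh=True),
    "unigene": FilterProfile("unigene", 1e-30, 90, min_pident=98.0),
    "uniprot": FilterProfile("uniprot", 1e-6, 30, min_ppos=100.0),
}


@dataclass
class GeneEvidence:
    lcn_id: str
    hits: dict[str, HomologyMatch] = field(default_factory=dict)
    classification: str = "none"


@dataclass
class GeneModel:
    """A reference-protein-anchored mosaic of mapped segments.

    ``segments`` are (ref_start, ref_end, source_id) in 1-based CDS
    nucleotide coordinates; unmapped reference positions are 'n'.
    """

    reference_protein_id: str
    species: str
    segments: list[tuple[int, int, str]]
    model_sequence: str
    covered_len: int
    conflict: bool = False


def filter_matches(
    matches: Sequence[HomologyMatch], profile: FilterProfile
) -> list[HomologyMatch]:
    """Retain matches passing the profile's e-value, alignment-length and
    similarity/identity thresholds (inclusive comparisons throughout)."""
    retained = []
    for m in matches:
        if m.evalue > profile.evalue_max or m.align_len < profile.min_align_len:
            continue
        if profile.min_ppos is not None:
            if m.ppos is None:
                raise ValueError(
                    f"profile {profile.reference_set!r} filters on ppos but match "
                    f"{m.query_id}/{m.subject_id} lacks it"
                )
            if m.ppos < profile.min_ppos:
                continue
        elif m.pident < (profile.min_pident or 0.0):
            continue
        retained.append(m)
    return retained


def _best_hits(matches: Iterable[HomologyMatch]) -> dict[str, HomologyMatch]:
    """Best hit per query: lowest e-value, ties by highest bitscore, then
    lexicographically smallest subject id."""
    best: dict[str, HomologyMatch] = {}
    for m in matches:
        cur = best.get(m.query_id)
        if cur is None or (m.evalue, -m.bitscore, m.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[m.query_id] = m
    return best


def reciprocal_best_hits(
    forward: Sequence[HomologyMatch], reverse: Sequence[HomologyMatch]
) -> list[tuple[str, str]]:
    """Pairs (q, s) where s is q's best forward hit and q is s's best
    reverse hit. Symmetric in the two directions."""
    fwd_best = _best_hits(forward)
    rev_best = _best_hits(reverse)
    pairs = []
    for q, m in sorted(fwd_best.items()):
        s = m.subject_id
        rm = rev_best.get(s)
        if rm is not None and rm.subject_id == q:
            pairs.append((q, s))
    return pairs


def deduplicate_singletons(
    matches: Sequence[HomologyMatch], contig_ids: set[str] | frozenset[str] = frozenset()
) -> list[HomologyMatch]:
    """Collapse redundant singletons covering the exact same subject
    interval — an MDA amplification-bias guard.

    Among singleton queries whose (subject_id, sstart, send) coincide
    exactly, one representative is kept: the longest aligned query, ties by
    lexicographic query id. Contigs (ids in ``contig_ids``) are never
    removed.
    """
    groups: dict[tuple[str, int, int], list[HomologyMatch]] = {}
    passthrough: list[HomologyMatch] = []
    for m in matches:
        if m.query_id in contig_ids:
            passthrough.append(m)
        else:
            groups.setdefault((m.subject_id, m.sstart, m.send), []).append(m)
    kept = list(passthrough)
    for group in groups.values():
        group.sort(key=lambda m: (-m.align_len, m.query_id))
        kept.append(group[0])
    order = {id(m): i for i, m in enumerate(matches)}
    kept.sort(key=lambda m: order[id(m)])
    return kept


def classify_gene_space(
    hits_by_reference: Mapping[str, Sequence[HomologyMatch]],
) -> tuple[list[GeneEvidence], dict[frozenset[str], int]]:
    """Partition sequences into conserved / non-conserved and count the
    proteome Venn regions.

    Conserved: >=1 retained hit in any grass proteome. Non-conserved: hits
    only in UniGene/UniProt. The Venn counts cover every non-empty subset
    of the four proteomes (conserved sequences only).
    """
    evidence: dict[str, GeneEvidence] = {}
    for ref_set, matches in hits_by_reference.items():
        for m in matches:
            ev = evidence.setdefault(m.query_id, GeneEvidence(lcn_id=m.query_id))
            cur = ev.hits.get(ref_set)
            if cur is None or (m.evalue, -m.bitscore) < (cur.evalue, -cur.bitscore):
                ev.hits[ref_set] = m

    venn: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(PROTEOME_PRECEDENCE) + 1)
        for sub in combinations(PROTEOME_PRECEDENCE, r)
    }
    for ev in evidence.values():
        proteome_hits = frozenset(ev.hits) & PROTEOME_SETS
        if proteome_hits:
            ev.classification = "conserved"
            venn[proteome_hits] += 1
        elif frozenset(ev.hits) & NONCONSERVED_SETS:
            ev.classification = "non_conserved"
        else:
            ev.classification = "none"
    return sorted(evidence.values(), key=lambda e: e.lcn_id), venn


def assign_reference(
    hits: Mapping[str, HomologyMatch], precedence: Sequence[str] = PROTEOME_PRECEDENCE
) -> tuple[str, HomologyMatch] | None:
    """Pick the anchoring reference for a sequence with hits in several
    proteomes, by fixed proteome precedence."""
    for ref_set in precedence:
        if ref_set in hits:
            return ref_set, hits[ref_set]
    return None


def protein_to_cds_interval(aa_start: int, aa_end: int) -> tuple[int, int]:
    """Protein-space 1-based residue interval -> CDS nucleotide interval."""
    return 3 * (aa_start - 1) + 1, 3 * aa_end


@dataclass
class MappedSegment:
    """One source sequence mapped onto a reference CDS (1-based)."""

    source_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    bases: str
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != self.ref_end - self.ref_start + 1:
            raise ValueError(
                f"segment {self.source_id}->{self.ref_id}: bases length "
                f"{len(self.bases)} != interval {self.ref_start}-{self.ref_end}"
            )


def build_gene_models(
    segments: Sequence[MappedSegment], reference_lengths: Mapping[str, int]
) -> list[GeneModel]:
    """Merge mapped segments per reference CDS into gap-filled models.

    Non-overlapping segments are concatenated with 'n' over unmapped
    reference positions. Overlapping segments are reconciled by keeping the
    segment with more aligned bases intact and trimming the other; if the
    trimmed region disagreed with the kept bases the model's conflict flag
    is raised.
    """
    by_ref: dict[str, list[MappedSegment]] = {}
    for seg in segments:
        ref_len = reference_lengths.get(seg.ref_id)
        if ref_len is None:
            raise ValueError(f"unknown reference {seg.ref_id!r}")
        if seg.ref_end > ref_len or seg.ref_start < 1:
            raise ValueError(
                f"segment {seg.ref_start}-{seg.ref_end} outside reference "
                f"{seg.ref_id!r} (length {ref_len})"
            )
        by_ref.setdefault(seg.ref_id, []).append(seg)

    models = []
    for ref_id in sorted(by_ref):
        ref_len = reference_lengths[ref_id]
        model = ["n"] * ref_len
        owner = [""] * ref_len
        conflict = False
        kept_segments: list[tuple[int, int, str]] = []
        # larger segments claim positions first; later (smaller) segments
        # are trimmed to the still-unclaimed positions
        ordered = sorted(by_ref[ref_id], key=lambda s: (-len(s.bases), s.source_id))
        for seg in ordered:
            placed: list[int] = []
            for pos in range(seg.ref_start, seg.ref_end + 1):
                base = seg.bases[pos - seg.ref_start]
                if owner[pos - 1]:
                    if model[pos - 1] != base:
                        conflict = True
                else:
                    model[pos - 1] = base
                    owner[pos - 1] = seg.source_id
                    placed.append(pos)
            for run_start, run_end in _runs(placed):
                kept_segments.append((run_start, run_end, seg.source_id))
        covered = sum(1 for b in owner if b)
        models.append(
            GeneModel(
                reference_protein_id=ref_id,
                species=by_ref[ref_id][0].species,
                segments=sorted(kept_segments),
                model_sequence="".join(model),
                covered_len=covered,
                conflict=conflict,
            )
        )
    return models


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    runs = []
    for p in positions:
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p)
        else:
            runs.append((p, p))
    return runs


def genic_fraction(
    n_models: int, mean_cds_len: float, chromosome_size: float
) -> tuple[float, float]:
    """(estimated coding length in bases, genic fraction in percent)."""
    if mean_cds_len <= 0 or chromosome_size <= 0 or n_models < 0:
        raise ValueError("inputs must be positive")
    coding_len = n_models * mean_cds_len
    return coding_len, round(100.0 * coding_len / chromosome_size, 2)


def genome_gene_estimate(
    fraction_pct: float, genome_size: float, mean_cds_len: float
) -> int:
    """Genome-wide gene count implied by a genic fraction, floored."""
    if genome_size <= 0 or mean_cds_len <= 0:
        raise ValueError("inputs must be positive")
    return int((fraction_pct / 100.0 * genome_size) / mean_cds_len)


def map_sequences_to_cds(
    sequences: Sequence, cds_by_id: Mapping[str, str], k: int = 21
) -> list[MappedSegment]:
    """Exact k-mer seeded ungapped mapper of sequences onto reference CDS.

    A deterministic internal mapper for synthetic runs; real analyses
    import external mapper output as MappedSegments.
    """
    index: dict[str, tuple[str, int]] = {}
    for ref_id, cds in cds_by_id.items():
        for i in range(len(cds) - k + 1):
            index.setdefault(cds[i : i + k], (ref_id, i))
    segments = []
    for rec in sequences:
        s = rec.sequence
        i = 0
        while i <= len(s) - k:
            hit = index.get(s[i : i + k])
            if hit is None:
                i += 1
                continue
            ref_id, rpos = hit
            cds = cds_by_id[ref_id]
            qs, rs = i, rpos
            while qs > 0 and rs > 0 and s[qs - 1] == cds[rs - 1]:
                qs -= 1
                rs -= 1
            qe, re_ = i + k - 1, rpos + k - 1
            while qe + 1 < len(s) and re_ + 1 < len(cds) and s[qe + 1] == cds[re_ + 1]:
                qe += 1
                re_ += 1
            segments.append(
                MappedSegment(
                    source_id=rec.id,
                    ref_id=ref_id,
                    ref_start=rs + 1,
                    ref_end=re_ + 1,
                    bases=s[qs : qe + 1],
                )
            )
            i = qe + 1
    return segments
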