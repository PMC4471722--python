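"""SNP discovery on chromosome-related transcripts and cross-genotype
classification.

Transcripts related to the sorted chromosome are selected by a stringent
homology filter (e-value <= 1e-30, identity >= 98%), chromosome reads are
piled up on them, single-position variants are called where a strict
majority of read bases differs from the transcript base, and calls are
filtered on mapped depth (3 <= depth <= 10) and proximity (>3 bp between
SNPs; both members of a close pair are dropped, transitively over
clusters — a guard against alignment-artifact clusters).

Variant positions found in the drought-tolerant genotype (TR) are then
transferred through pairwise transcript alignments to the second
genotype (TTD) and, requiring coverage and base consistency between the
drought and control assemblies of each genotype, classified against the
chromosome base (B5) into:

- Group 1: TR differs, TTD agrees with the chromosome (TR-specific),
- Group 2: TR and TTD agree but differ from the chromosome,
- Group 3: all three pairwise distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .seqio import HomologyMatch, ReadRecord, SamAlignment


@dataclass
class SNPConfig:
    min_depth: int = 3
    max_depth: int = 10
    #: ">3 bp between SNPs": pairs at distance <= 3 are removed
    min_spacing: int = 4
    transcript_evalue_max: float = 1e-30
    transcript_pident_min: float = 98.0

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth > max_depth")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")


@dataclass
class SiteCall:
    """A single-position variant with its pileup evidence."""

    transcript_id: str
    position: int  # 1-based on the transcript
    transcript_base: str
    read_consensus_base: str
    depth: int
    allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth != sum(self.allele_counts.values()):
            raise ValueError(
                f"{self.transcript_id}:{self.position}: depth != sum of allele counts"
            )


@dataclass
class SharedSNP:
    tr_transcript_id: str
    tr_position: int
    tr_base: str
    ttd_base: str | None
    b5_base: str | None
    coverage_ok: bool
    consistent: bool
    group: int | None  # 1, 2, 3 or None
    homoeolog_risk: bool = False


def select_5b_transcripts(
    matches: Sequence[HomologyMatch], config: SNPConfig | None = None
) -> set[str]:
    """Transcripts with >=1 match passing both thresholds (inclusive)."""
    config = config or SNPConfig()
    return {
        m.query_id
        for m in matches
        if m.evalue <= config.transcript_evalue_max
        and m.pident >= config.transcript_pident_min
    }


def homoeolog_risk_flags(
    matches: Sequence[HomologyMatch], config: SNPConfig | None = None
) -> set[str]:
    """Transcripts with >=2 strong matches: candidates for confusion with
    highly similar homoeologous (e.g. 5A-like) or paralogous loci."""
    config = config or SNPConfig()
    strong: dict[str, int] = {}
    for m in matches:
        if m.evalue <= config.transcript_evalue_max and m.pident >= config.transcript_pident_min:
            strong[m.query_id] = strong.get(m.query_id, 0) + 1
    return {t for t, n in strong.items() if n >= 2}


def call_variants(
    alignments: Sequence[SamAlignment],
    transcripts: Mapping[str, str],
    selected: set[str] | None = None,
) -> list[SiteCall]:
    """Pileup-based variant calling.

    Per transcript position, depth counts every aligned read base
    (positions inside alignment gaps contribute nothing). A variant is
    emitted where the strict-majority read base differs from the
    transcript base; majority ties emit no call.
    """
    selected = selected if selected is not None else set(transcripts)
    pileup: dict[tuple[str, int], dict[str, int]] = {}
    for aln in alignments:
        if aln.target_id not in selected:
            raise ValueError(f"alignment to unselected transcript {aln.target_id!r}")
        if aln.read_sequence is None:
            raise ValueError(f"alignment of {aln.read_id!r} carries no read sequence")
        for read_pos, ref_pos in aln.aligned_pairs:
            base = aln.read_sequence[read_pos - 1].upper()
            counts = pileup.setdefault((aln.target_id, ref_pos), {})
            counts[base] = counts.get(base, 0) + 1

    calls: list[SiteCall] = []
    for (tid, pos), counts in sorted(pileup.items()):
        ref_base = transcripts[tid][pos - 1].upper()
        depth = sum(counts.values())
        best = max(counts.values())
        leaders = [b for b, n in counts.items() if n == best]
        if len(leaders) != 1:
            continue  # majority tie: no call
        consensus = leaders[0]
        if consensus != ref_base:
            calls.append(
                SiteCall(
                    transcript_id=tid,
                    position=pos,
                    transcript_base=ref_base,
                    read_consensus_base=consensus,
                    depth=depth,
                    allele_counts=dict(counts),
                )
            )
    return calls


def call_variants_from_pileup(
    pileups: Mapping[tuple[str, int], Mapping[str, int]],
    transcripts: Mapping[str, str],
) -> list[SiteCall]:
    """Variant calling from precomputed per-position allele counts (the
    internal pileup interface)."""
    calls = []
    for (tid, pos), counts in sorted(pileups.items()):
        ref_base = transcripts[tid][pos - 1].upper()
        depth = sum(counts.values())
        best = max(counts.values())
        leaders = [b for b, n in counts.items() if n == best]
        if len(leaders) == 1 and leaders[0] != ref_base:
            calls.append(
                SiteCall(tid, pos, ref_base, leaders[0], depth, dict(counts))
            )
    return calls


def filter_variants(calls: Sequence[SiteCall], config: SNPConfig | None = None) -> list[SiteCall]:
    """Depth filter (inclusive at both bounds) then proximity filter: on
    each transcript, every call within ``min_spacing − 1`` bases of another
    surviving-depth call is removed (both members, transitively over
    clusters). Idempotent."""
    config = config or SNPConfig()
    by_depth = [c for c in calls if config.min_depth <= c.depth <= config.max_depth]
    by_transcript: dict[str, list[SiteCall]] = {}
    for c in by_depth:
        by_transcript.setdefault(c.transcript_id, []).append(c)
    kept: list[SiteCall] = []
    for tcalls in by_transcript.values():
        tcalls.sort(key=lambda c: c.position)
        drop = set()
        for a, b in zip(tcalls, tcalls[1:]):
            if b.position - a.position < config.min_spacing:
                drop.add(id(a))
                drop.add(id(b))
        kept.extend(c for c in tcalls if id(c) not in drop)
    kept.sort(key=lambda c: (c.transcript_id, c.position))
    return kept


def snp_frequency(
    retained: Sequence[SiteCall], transcript_lengths: Mapping[str, int]
) -> float | None:
    """Average bases per SNP over the selected transcript set; None
    (absent, not zero) when no SNPs were retained."""
    if not retained:
        return None
    total = sum(transcript_lengths.values())
    return total / len(retained)


# ---------------------------------------------------------------------------
# position transfer and classification


@dataclass
class TransferredPosition:
    transcript_id: str
    position: int
    other_transcript_id: str | None
    other_position: int | None
    other_base: str | None
    covered: bool
    ambiguous: bool = False


def _best_match_per_query(matches: Sequence[HomologyMatch]) -> dict[str, tuple[HomologyMatch, bool]]:
    """Best subject per query by bitscore; second value flags ambiguity
    (>=2 subjects passing the filter)."""
    grouped: dict[str, list[HomologyMatch]] = {}
    for m in matches:
        grouped.setdefault(m.query_id, []).append(m)
    out = {}
    for q, ms in grouped.items():
        ms.sort(key=lambda m: (-m.bitscore, m.evalue, m.subject_id))
        out[q] = (ms[0], len({m.subject_id for m in ms}) > 1)
    return out


def transfer_positions(
    snps: Sequence[SiteCall],
    tr_transcripts: Mapping[str, str],
    other_transcripts: Mapping[str, str],
    matches: Sequence[HomologyMatch],
    config: SNPConfig | None = None,
) -> list[TransferredPosition]:
    """Map each SNP position onto the homologous base of the best-matching
    transcript in another sample via global pairwise alignment.

    Matches must pass the transcript filter; multi-match transcripts are
    resolved to the highest-bitscore subject with the ambiguity flagged.
    Positions falling in alignment gaps are flagged uncovered.
    """
    config = config or SNPConfig()
    passing = [
        m
        for m in matches
        if m.evalue <= config.transcript_evalue_max
        and m.pident >= config.transcript_pident_min
    ]
    best = _best_match_per_query(passing)

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-1,
    )
    position_maps: dict[tuple[str, str], dict[int, int]] = {}
    results = []
    for snp in snps:
        entry = best.get(snp.transcript_id)
        if entry is None:
            results.append(
                TransferredPosition(snp.transcript_id, snp.position, None, None, None, False)
            )
            continue
        match, ambiguous = entry
        other_id = match.subject_id
        key = (snp.transcript_id, other_id)
        if key not in position_maps:
            alignment = aligner.align(
                tr_transcripts[snp.transcript_id], other_transcripts[other_id]
            )[0]
            pmap = {}
            for (qs, qe), (ss, se) in zip(*alignment.aligned):
                for off in range(qe - qs):
                    pmap[qs + off + 1] = ss + off + 1
            position_maps[key] = pmap
        other_pos = position_maps[key].get(snp.position)
        if other_pos is None:
            results.append(
                TransferredPosition(
                    snp.transcript_id, snp.position, other_id, None, None, False, ambiguous
                )
            )
        else:
            results.append(
                TransferredPosition(
                    snp.transcript_id,
                    snp.position,
                    other_id,
                    other_pos,
                    other_transcripts[other_id][other_pos - 1].upper(),
                    True,
                    ambiguous,
                )
            )
    return results


def classify_shared(
    tr_base_drought: str | None,
    tr_base_control: str | None,
    ttd_base_drought: str | None,
    ttd_base_control: str | None,
    b5_base: str | None,
    tr_transcript_id: str = "",
    tr_position: int = 0,
) -> SharedSNP:
    """Classify one position across both genotypes and the chromosome.

    Requires coverage in every sample and drought/control consistency
    within each genotype; then with TR, TTD and B5 the three bases:
    Group 1 iff TR != TTD and TTD == B5; Group 2 iff TR == TTD != B5;
    Group 3 iff all three pairwise distinct.
    """
    bases = [tr_base_drought, tr_base_control, ttd_base_drought, ttd_base_control, b5_base]
    coverage_ok = all(b is not None for b in bases)
    if not coverage_ok:
        return SharedSNP(
            tr_transcript_id, tr_position,
            tr_base_drought or "?", ttd_base_drought, b5_base,
            coverage_ok=False, consistent=False, group=None,
        )
    tr_d, tr_c, ttd_d, ttd_c, b5 = (b.upper() for b in bases)
    consistent = tr_d == tr_c and ttd_d == ttd_c
    if not consistent:
        return SharedSNP(
            tr_transcript_id, tr_position, tr_d, ttd_d, b5,
            coverage_ok=True, consistent=False, group=None,
        )
    tr, ttd = tr_d, ttd_d
    if tr != ttd and ttd == b5:
        group: int | None = 1
    elif tr == ttd and tr != b5:
        group = 2
    elif tr != ttd and ttd != b5 and tr != b5:
        group = 3
    else:
        group = None
    return SharedSNP(
        tr_transcript_id, tr_position, tr, ttd, b5,
        coverage_ok=True, consistent=True, group=group,
    )


# ---------------------------------------------------------------------------
# internal test mapper


def map_reads_to_transcripts(
    reads: Sequence[ReadRecord],
    transcripts: Mapping[str, str],
    k: int = 21,
) -> list[SamAlignment]:
    """Exact 21-mer seed + ungapped extension mapper for synthetic reads
    (edit-free by construction); real data enters as minimal SAM."""
    index: dict[str, tuple[str, int]] = {}
    for tid, seq in transcripts.items():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            index.setdefault(s[i : i + k], (tid, i))
    alignments = []
    for read in reads:
        s = read.sequence.upper()
        placement = None
        for i in range(0, max(1, len(s) - k + 1), 5):
            hit = index.get(s[i : i + k])
            if hit:
                tid, tpos = hit
                placement = (tid, tpos - i)  # 0-based target start of read
                break
        if placement is None:
            continue
        tid, t0 = placement
        target = transcripts[tid]
        q_lo = max(0, -t0)
        q_hi = min(len(s), len(target) - t0)
        if q_hi <= q_lo:
            continue
        pairs = [(q + 1, t0 + q + 1) for q in range(q_lo, q_hi)]
        alignments.append(
            SamAlignment(read.id, tid, t0 + q_lo + 1, pairs, read_sequence=s)
        )
    return alignments
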