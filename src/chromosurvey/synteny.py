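"""Windowed synteny analysis against model-grass genomes.

Conserved genes are placed on model-genome coordinates (gene midpoints),
gene densities are counted in tumbling or sliding windows, dense 1 Mb
windows are merged into syntenic blocks, and genes whose cross-species
chromosome assignments disagree with the orthologous chromosome set are
classified as lineage-rearranged ("moved").
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: default window geometry (bases)
DENSITY_WINDOW = 500_000
RIBBON_WINDOW = 1_000_000
HEATMAP_STEP = 50_000
#: block threshold is strict: a window qualifies with MORE than this many members
RIBBON_MIN_MEMBERS = 100


@dataclass
class SyntenyAssignment:
    """One conserved gene placed on a model genome (midpoint coordinate)."""

    lcn_id: str
    species: str
    chromosome: str
    position: int


@dataclass
class SyntenyBlock:
    species: str
    chromosome: str
    window_start: int
    window_end: int
    member_count: int


def load_synteny_map(path: str | Path | None = None) -> list[frozenset[tuple[str, str]]]:
    """Load the inter-model synteny map: groups of mutually colinear
    (species, chromosome) pairs. The bundled map carries the wheat
    group-5 relationships (Bd1-Os3-Sb1, Bd4-Os9-Sb2, Bd4-Os12)."""
    if path is None:
        ref = resources.files("chromosurvey") / "_data" / "group5_synteny_map.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    groups: dict[str, set[tuple[str, str]]] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        groups.setdefault(row["group_id"], set()).add(
            (row["species"], str(row["chromosome"]))
        )
    return [frozenset(g) for g in groups.values()]


def orthologous_chromosomes(
    synteny_map: Sequence[frozenset[tuple[str, str]]],
) -> dict[str, set[str]]:
    """Per-species set of chromosomes orthologous to the target group."""
    out: dict[str, set[str]] = {}
    for group in synteny_map:
        for species, chrom in group:
            out.setdefault(species, set()).add(chrom)
    return out


def windowed_density(
    assignments: Sequence[SyntenyAssignment],
    window: int = DENSITY_WINDOW,
    step: int | None = None,
    chromosome_length: int | None = None,
) -> pd.DataFrame:
    """Per-window gene counts over half-open windows [start, start+window).

    ``step`` defaults to ``window`` (tumbling); a smaller step gives
    sliding (heatmap-style) windows where shared genes are counted in each
    overlapping window. Positions are 1-based; windows start at 1.
    """
    if window <= 0 or (step is not None and step <= 0):
        raise ValueError("window and step must be positive")
    step = step or window
    rows = []
    by_chrom: dict[tuple[str, str], list[int]] = {}
    for a in assignments:
        by_chrom.setdefault((a.species, a.chromosome), []).append(a.position)
    for (species, chrom), positions in sorted(by_chrom.items()):
        positions.sort()
        extent = chromosome_length or positions[-1]
        start = 1
        while start <= extent:
            end = start + window  # half-open bound
            count = sum(1 for p in positions if start <= p < end)
            rows.append(
                {
                    "species": species,
                    "chromosome": chrom,
                    "window_start": start,
                    "window_end": end - 1,
                    "count": count,
                }
            )
            start += step
    return pd.DataFrame(
        rows, columns=["species", "chromosome", "window_start", "window_end", "count"]
    )


def call_blocks(
    assignments: Sequence[SyntenyAssignment],
    window: int = RIBBON_WINDOW,
    min_members: int = RIBBON_MIN_MEMBERS,
    chromosome_lengths: Mapping[tuple[str, str], int] | None = None,
) -> list[SyntenyBlock]:
    """Call syntenic blocks: tumbling windows with member_count strictly
    greater than ``min_members``; adjacent qualifying windows are merged
    into one block with summed members."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    density = windowed_density(assignments, window=window)
    blocks: list[SyntenyBlock] = []
    for (species, chrom), sub in density.groupby(["species", "chromosome"], sort=True):
        open_block: SyntenyBlock | None = None
        sub = sub.sort_values("window_start")
        for ws, we, count in zip(sub["window_start"], sub["window_end"], sub["count"]):
            if count > min_members:
                if open_block is not None and ws == open_block.window_end + 1:
                    open_block.window_end = int(we)
                    open_block.member_count += int(count)
                else:
                    if open_block is not None:
                        blocks.append(open_block)
                    open_block = SyntenyBlock(
                        species, chrom, int(ws), int(we), int(count)
                    )
            else:
                if open_block is not None:
                    blocks.append(open_block)
                    open_block = None
        if open_block is not None:
            blocks.append(open_block)
    return blocks


def classify_moved(
    chromosome_by_species: Mapping[str, str],
    orthologous_sets: Mapping[str, set[str]] | None = None,
    synteny_map: Sequence[frozenset[tuple[str, str]]] | None = None,
    all_species: Sequence[str] = ("Bd", "Os", "Sb"),
) -> str:
    """Classify one gene's cross-species placements.

    - ``syntenic``: every species with an assignment maps to an
      orthologous chromosome.
    - ``moved_in_wheat``: all species agree on non-orthologous chromosomes
      that are mutually colinear with each other (the gene moved in the
      wheat lineage).
    - ``moved_in_other:<sp>``: exactly one species deviates from an
      otherwise orthologous placement (the gene moved in that lineage).
    - ``unresolved`` otherwise.
    """
    if not chromosome_by_species:
        raise ValueError("no species assignment given")
    if synteny_map is None:
        synteny_map = load_synteny_map()
    if orthologous_sets is None:
        # orthologous to the target wheat group: always the bundled
        # group-5 relationships, independent of any wider colinearity map
        orthologous_sets = orthologous_chromosomes(load_synteny_map())

    on_ortho = {
        sp: str(chrom) in orthologous_sets.get(sp, set())
        for sp, chrom in chromosome_by_species.items()
    }
    if all(on_ortho.values()):
        return "syntenic"
    if not any(on_ortho.values()):
        placement = frozenset(
            (sp, str(chrom)) for sp, chrom in chromosome_by_species.items()
        )
        if len(placement) == 1 or any(placement <= group for group in synteny_map):
            return "moved_in_wheat"
        return "unresolved"
    deviants = [sp for sp, ok in on_ortho.items() if not ok]
    if len(deviants) == 1:
        return f"moved_in_other:{deviants[0]}"
    return "unresolved"


def circos_links(
    assignments: Sequence[SyntenyAssignment],
    target_name: str = "Tdic5B",
    target_length: int = 840_000_000,
) -> list[str]:
    """Circos-compatible link lines from the target chromosome to each
    assignment's model-genome window (text export only)."""
    lines = []
    n = max(len(assignments), 1)
    span = target_length // n if n else target_length
    for i, a in enumerate(sorted(assignments, key=lambda a: (a.species, a.chromosome, a.position))):
        t_start = i * span + 1
        lines.append(
            f"{target_name} {t_start} {t_start + span - 1} "
            f"{a.species}{a.chromosome} {a.position} {a.position + 1}"
        )
    return lines


def export_blocks_tsv(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species": b.species,
                "chromosome": b.chromosome,
                "window_start": b.window_start,
                "window_end": b.window_end,
                "member_count": b.member_count,
            }
            for b in blocks
        ]
    ).to_csv(path, sep="\t", index=False)
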