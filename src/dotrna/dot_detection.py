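"""Disorder-to-order transition (DOT) detection.

A DOT residue is disordered (listed in REMARK 465, no coordinates) in the
free protein but ordered (atom-bearing) in the RNA-bound complex of the same
sequence. Maximal runs of at least three consecutive DOT residues form DOT
regions, the unit of all downstream interface statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio.Align import PairwiseAligner

from .structure_io import ResidueKey, Structure

MIN_REGION_LENGTH = 3
# length histogram bins reproducing the narrative anchors "three to 10
# residues" and "more than 50 residues"; configurable in region_summary
DEFAULT_LENGTH_BINS: Tuple[Tuple[int, Optional[int]], ...] = (
    (3, 10), (11, 20), (21, 50), (51, None))


class MappingError(ValueError):
    """Free and bound structures cannot be paired (identity < 99%)."""


@dataclass
class StructurePair:
    """A free protein and its RNA-bound complex with residue correspondence."""

    free: Structure
    bound: Structure
    mapping: Dict[ResidueKey, ResidueKey]  # free residue -> bound residue

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("mapping is not injective")


@dataclass(frozen=True)
class DOTRegion:
    """Maximal run of >=3 consecutive DOT residues in the bound structure."""

    chain_id: str
    residues: Tuple[ResidueKey, ...]

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> ResidueKey:
        return self.residues[0]

    @property
    def end(self) -> ResidueKey:
        return self.residues[-1]


# ---------------------------------------------------------------------------
# residue correspondence

_ALIGNER = PairwiseAligner(mode="global", match_score=1.0, mismatch_score=-1.0,
                           open_gap_score=-2.0, extend_gap_score=-0.5)

IDENTITY_CUTOFF = 0.99  # free/bound pairing criterion


def _align_chains(free_seq: str, bound_seq: str) -> List[Tuple[int, int]]:
    """Aligned position pairs (free index, bound index) of the best global alignment."""
    aln = _ALIGNER.align(free_seq.upper(), bound_seq.upper())[0]
    pairs: List[Tuple[int, int]] = []
    for (fs, fe), (bs, be) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend(zip(range(fs, fe), range(bs, be)))
    return pairs


def build_mapping(free: Structure, bound: Structure,
                  chain_pairs: Optional[Sequence[Tuple[str, str]]] = None,
                  ) -> Dict[ResidueKey, ResidueKey]:
    """Build the free->bound residue correspondence for protein chains.

    Residues are matched by identical author numbering when the two chains
    agree; otherwise by global alignment of the full sequences (observed +
    missing, in numbering order). Either way the pairing must reach >= 99%
    identity over aligned positions, the criterion for calling the two
    structures the same protein; below it :class:`MappingError` is raised.

    ``chain_pairs`` (free chain id, bound chain id) overrides the automatic
    chain pairing, for free structures whose chains cannot be matched by id.
    """
    free_chains = free.chains("protein")
    bound_chains = bound.chains("protein")
    if not free_chains or not bound_chains:
        raise MappingError("both structures need at least one protein chain")

    if chain_pairs is None:
        common = [c for c in free_chains if c in bound_chains]
        if len(common) == len(free_chains) == len(bound_chains):
            chain_pairs = [(c, c) for c in common]
        else:  # fall back to pairing in order
            chain_pairs = list(zip(free_chains, bound_chains))

    mapping: Dict[ResidueKey, ResidueKey] = {}
    for fc, bc in chain_pairs:
        fkeys = free.chain_residues(fc)
        bkeys = bound.chain_residues(bc)
        # fast path: identical author numbering
        fnum = [(k.seq_num, k.icode) for k in fkeys]
        bnum = [(k.seq_num, k.icode) for k in bkeys]
        if fnum == bnum:
            same = sum(1 for a, b in zip(fkeys, bkeys) if a.res_name == b.res_name)
            if same / len(fkeys) >= IDENTITY_CUTOFF:
                mapping.update(dict(zip(fkeys, bkeys)))
                continue
        pairs = _align_chains(free.sequence(fc), bound.sequence(bc))
        if not pairs:
            raise MappingError(f"chains {fc}/{bc}: not the same protein (no alignment)")
        ident = sum(1 for i, j in pairs
                    if fkeys[i].res_name == bkeys[j].res_name) / len(pairs)
        if ident < IDENTITY_CUTOFF:
            raise MappingError(
                f"chains {fc}/{bc}: not the same protein (identity {ident:.1%} < 99%)")
        mapping.update({fkeys[i]: bkeys[j] for i, j in pairs})
    return mapping


# ---------------------------------------------------------------------------
# DOT residues and regions

def find_dot_residues(pair: StructurePair) -> Set[ResidueKey]:
    """DOT residues in the bound frame: missing free-side, atom-bearing bound-side.

    Only REMARK 465 absence counts as disorder — residues with coordinates,
    however mobile, are never DOT.
    """
    bound_observed = {a.key for a in pair.bound.atoms}
    free_missing = set(pair.free.missing)
    out: Set[ResidueKey] = set()
    for fkey, bkey in pair.mapping.items():
        if fkey in free_missing and bkey in bound_observed:
            out.add(bkey)
    return out


def _consecutive(a: ResidueKey, b: ResidueKey) -> bool:
    """b directly follows a: same chain, author number advances by 0 or 1.

    Insertion-coded residues (52, 52A) share a number and are treated as
    consecutive; a numbering jump (30 -> 41) breaks continuity even when the
    gap is not listed as missing.
    """
    return (a.chain_id == b.chain_id
            and b.seq_num - a.seq_num in (0, 1)
            and b.order > a.order)


def segment_regions(dot_residues: Iterable[ResidueKey],
                    min_length: int = MIN_REGION_LENGTH) -> List[DOTRegion]:
    """Maximal runs of consecutive DOT residues; runs shorter than 3 discarded."""
    ordered = sorted(dot_residues, key=lambda k: k.order)
    regions: List[DOTRegion] = []
    run: List[ResidueKey] = []
    for k in ordered:
        if run and _consecutive(run[-1], k):
            run.append(k)
        else:
            if len(run) >= min_length:
                regions.append(DOTRegion(run[0].chain_id, tuple(run)))
            run = [k]
    if len(run) >= min_length:
        regions.append(DOTRegion(run[0].chain_id, tuple(run)))
    return regions


def detect(pair: StructurePair) -> List[DOTRegion]:
    """Convenience: DOT residues then maximal regions for one structure pair."""
    return segment_regions(find_dot_residues(pair))


# ---------------------------------------------------------------------------
# dataset-level summaries

@dataclass
class RegionSummary:
    """Distribution of region counts per complex and of region lengths."""

    regions_per_complex: "Counter[int]"
    length_histogram: Dict[str, int]
    bins: Tuple[Tuple[int, Optional[int]], ...]

    @property
    def fraction_below(self) -> Dict[int, float]:
        """Fraction of complexes with fewer than k regions, for each observed k."""
        total = sum(self.regions_per_complex.values())
        out = {}
        for k in range(1, max(self.regions_per_complex, default=0) + 2):
            out[k] = sum(v for n, v in self.regions_per_complex.items() if n < k) / total
        return out


def _bin_label(lo: int, hi: Optional[int]) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


def region_summary(regions_per_complex: Sequence[Sequence[DOTRegion]],
                   bins: Tuple[Tuple[int, Optional[int]], ...] = DEFAULT_LENGTH_BINS,
                   ) -> RegionSummary:
    """Summarise DOT regions over a dataset of complexes."""
    counts = Counter(len(regions) for regions in regions_per_complex)
    hist = {_bin_label(lo, hi): 0 for lo, hi in bins}
    for regions in regions_per_complex:
        for region in regions:
            for lo, hi in bins:
                if region.length >= lo and (hi is None or region.length <= hi):
                    hist[_bin_label(lo, hi)] += 1
                    break
    return RegionSummary(regions_per_complex=counts, length_histogram=hist, bins=bins)
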