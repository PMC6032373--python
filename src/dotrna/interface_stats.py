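"""Protein–RNA interface statistics.

Residue–nucleotide contacts at a distance cutoff (minimum heavy-atom
distance, 3.5 Å and 6 Å by default), per-amino-acid binding frequencies and
propensities over DOT regions, bootstrap standard errors over complexes,
a depletion significance test, and the secondary-structure cross-tabulations
of contacts on both the protein and the RNA side.

Definitions (per amino-acid type i):

    N_ip   residues of type i in the protein
    N_p    residues in the protein (all types)
    N_id   residues of type i inside DOT regions
    N_ib   residues of type i contacting RNA anywhere in the protein
    N_ibd  residues of type i contacting RNA within DOT regions

    frequency of binding in DOT      = N_ibd / N_id
    frequency of DOT among binders   = N_ibd / N_ib
    propensity                       = (N_ibd / N_id) / (N_ip / N_p)

On the RNA side, N_idt counts distinct nucleotides contacting DOT residues
and N_prot distinct nucleotides contacting any protein residue.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import binom

from .structure_io import (AMINO_ACIDS, NUCLEOTIDES, ProteinSS, ResidueKey,
                           Structure)

DEFAULT_CUTOFFS = (3.5, 6.0)


@dataclass(frozen=True)
class ContactRecord:
    """One protein-residue / nucleotide pair within the distance cutoff."""

    protein_residue: ResidueKey
    nucleotide: ResidueKey
    min_distance: float
    in_dot: bool = False


@dataclass
class CountTable:
    """Per-amino-acid counts feeding the frequency and propensity statistics.

    ``counts`` is indexed by 3-letter residue type with integer columns
    ``n_ip``, ``n_id``, ``n_ib``, ``n_ibd``; ``n_p`` is the total residue
    count. Tables from several complexes add.
    """

    counts: pd.DataFrame
    n_p: int

    def __post_init__(self) -> None:
        c = self.counts
        if (c < 0).any().any():
            raise ValueError("counts must be non-negative")
        if (c["n_ibd"] > c[["n_id", "n_ib"]].min(axis=1)).any():
            raise ValueError("N_ibd must not exceed min(N_id, N_ib)")
        if (c["n_ib"] > c["n_ip"]).any() or c["n_ip"].sum() > self.n_p:
            raise ValueError("N_ib <= N_ip and sum(N_ip) <= N_p must hold")

    def __add__(self, other: "CountTable") -> "CountTable":
        return CountTable(self.counts.add(other.counts, fill_value=0).astype(int),
                          self.n_p + other.n_p)

    @staticmethod
    def empty() -> "CountTable":
        df = pd.DataFrame(0, index=list(AMINO_ACIDS),
                          columns=["n_ip", "n_id", "n_ib", "n_ibd"], dtype=int)
        return CountTable(df, 0)


@dataclass
class StatResult:
    """A statistic with its bootstrap standard error."""

    estimate: pd.Series
    se: pd.Series
    n_samples: int


# ---------------------------------------------------------------------------
# contact detection

def find_contacts(structure: Structure, cutoff: float,
                  dot_residues: Optional[Set[ResidueKey]] = None,
                  ) -> List[ContactRecord]:
    """Residue–nucleotide contacts: minimum heavy-atom distance <= cutoff.

    Hydrogens are excluded. Each residue/nucleotide pair is reported once,
    with its minimum distance; the boundary is closed (d == cutoff counts).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot_keys = structure.residues("protein")
    rna_keys = structure.residues("rna")
    if not rna_keys:
        raise ValueError("structure has no RNA chain")
    if not prot_keys:
        raise ValueError("structure has no protein chain")

    pxyz, patoms = structure.coords(prot_keys, heavy_only=True)
    nxyz, natoms = structure.coords(rna_keys, heavy_only=True)
    pres = {k: i for i, k in enumerate(prot_keys)}
    nres = {k: i for i, k in enumerate(rna_keys)}
    pidx = np.array([pres[a.key] for a in patoms])
    nidx = np.array([nres[a.key] for a in natoms])

    tree_p, tree_n = cKDTree(pxyz), cKDTree(nxyz)
    pairs = tree_p.sparse_distance_matrix(tree_n, max_distance=cutoff,
                                          output_type="coo_matrix")
    best: Dict[Tuple[int, int], float] = {}
    for ai, aj, d in zip(pairs.row, pairs.col, pairs.data):
        rk = (pidx[ai], nidx[aj])
        if d < best.get(rk, np.inf):
            best[rk] = d
    dot = dot_residues or set()
    out = [ContactRecord(prot_keys[i], rna_keys[j], float(d),
                         prot_keys[i] in dot)
           for (i, j), d in best.items()]
    out.sort(key=lambda c: (c.protein_residue.order, c.nucleotide.order))
    return out


# ---------------------------------------------------------------------------
# count-table construction

def build_count_table(structure: Structure, dot_residues: Set[ResidueKey],
                      contacts: Sequence[ContactRecord]) -> CountTable:
    """Tally the per-type counts for one complex from its contacts and DOT set."""
    table = CountTable.empty()
    c = table.counts
    prot = structure.residues("protein")
    binders = {r.protein_residue for r in contacts}
    for k in prot:
        if k.res_name not in c.index:
            continue
        c.at[k.res_name, "n_ip"] += 1
        if k in dot_residues:
            c.at[k.res_name, "n_id"] += 1
        if k in binders:
            c.at[k.res_name, "n_ib"] += 1
            if k in dot_residues:
                c.at[k.res_name, "n_ibd"] += 1
    return CountTable(c, len(prot))


# ---------------------------------------------------------------------------
# frequencies and propensity

def freq_binding_in_dot(table: CountTable) -> pd.Series:
    """N_ibd / N_id per type; NaN (undefined) where the type has no DOT residues."""
    c = table.counts
    return (c["n_ibd"] / c["n_id"].where(c["n_id"] > 0)).rename("freq_binding_in_dot")


def freq_dot_among_binders(table: CountTable) -> pd.Series:
    """N_ibd / N_ib per type; NaN where the type never binds RNA."""
    c = table.counts
    return (c["n_ibd"] / c["n_ib"].where(c["n_ib"] > 0)).rename("freq_dot_among_binders")


def propensity(table: CountTable) -> pd.Series:
    """(N_ibd/N_id) / (N_ip/N_p) per type; 1 means no enrichment over composition."""
    c = table.counts
    num = c["n_ibd"] / c["n_id"].where(c["n_id"] > 0)
    den = c["n_ip"].where(c["n_ip"] > 0) / table.n_p
    return (num / den).rename("propensity")


# ---------------------------------------------------------------------------
# bootstrap over complexes

def bootstrap_stat(tables: Sequence[CountTable],
                   statistic: Callable[[CountTable], pd.Series],
                   n_samples: int = 1000,
                   seed: Optional[int] = None) -> StatResult:
    """Bootstrap SE of a count-table statistic, resampling whole complexes.

    Each bootstrap sample draws as many complexes as the dataset holds, with
    replacement; the statistic is evaluated on the pooled counts of the
    sample. The point estimate uses the full dataset. Deterministic for a
    fixed seed.
    """
    if len(tables) < 2:
        raise ValueError("bootstrap needs at least two complexes")
    rng = np.random.default_rng(seed)
    pooled = sum(tables[1:], tables[0])
    point = statistic(pooled)
    point = point if isinstance(point, pd.Series) else pd.Series({"value": point})

    # stack counts for vectorised pooling
    mats = np.stack([t.counts.to_numpy() for t in tables])        # (n, 20, 4)
    nps = np.array([t.n_p for t in tables])
    template = tables[0].counts
    n = len(tables)
    draws = rng.integers(0, n, size=(n_samples, n))
    samples = np.empty((n_samples, len(point)))
    for s in range(n_samples):
        idx = draws[s]
        pooled_s = CountTable(
            pd.DataFrame(mats[idx].sum(axis=0), index=template.index,
                         columns=template.columns),
            int(nps[idx].sum()))
        val = statistic(pooled_s)
        samples[s] = (val.to_numpy() if isinstance(val, pd.Series)
                      else np.array([val]))
    import warnings as _warnings
    with _warnings.catch_warnings():
        # columns NaN in every sample (e.g. a type never seen in DOT) stay NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        se = pd.Series(np.nanstd(samples, axis=0, ddof=1), index=point.index,
                       name="bootstrap_se")
    return StatResult(estimate=point, se=se, n_samples=n_samples)


# ---------------------------------------------------------------------------
# reported percentages and the depletion test

def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up, the convention of the reported tables."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def relative_percentage(n_sub: int, n_total: int, decimals: int = 1) -> float:
    """100 * n_sub / n_total rounded half-up; NaN when the denominator is 0."""
    if n_total == 0:
        return float("nan")
    return round_half_up(100.0 * n_sub / n_total, decimals)


def depletion_test(observed: int, expected_fraction: float, n_trials: int) -> float:
    """Exact binomial tail P(X <= observed) at the expected fraction.

    Used to test whether seeing `observed` (e.g. zero Met or Trp) among
    `n_trials` DOT interface residues is consistent with the background
    fraction. For observed = 0 this is (1 - p)^n.
    """
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected_fraction must be in (0, 1)")
    if observed < 0 or n_trials <= 0:
        raise ValueError("need observed >= 0 and n_trials > 0")
    return float(binom.cdf(observed, n_trials, expected_fraction))


# ---------------------------------------------------------------------------
# contact cross-tabulations

def aa_nt_contact_matrix(contacts: Sequence[ContactRecord],
                         normalize: bool = True) -> pd.DataFrame:
    """20x4 amino-acid × nucleotide contact-pair tally.

    With ``normalize`` (default) entries are divided by the total number of
    contact pairs so the matrix sums to 1; otherwise raw counts.
    """
    mat = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(NUCLEOTIDES))
    for c in contacts:
        aa, nt = c.protein_residue.res_name, c.nucleotide.res_name
        if aa in mat.index and nt in mat.columns:
            mat.at[aa, nt] += 1
    total = mat.to_numpy().sum()
    if normalize and total > 0:
        mat /= total
    return mat


def protein_ss_crosstab(dot_residues: Set[ResidueKey],
                        contacts: Sequence[ContactRecord],
                        ss: ProteinSS,
                        decimals: int = 1) -> pd.DataFrame:
    """Per 3-state class: binding DOT residues, all DOT residues, relative %.

    Rows helix/sheet/other with columns ``n_idt`` (DOT residues contacting
    RNA), ``n_d`` (all DOT residues) and ``relative_binding_pct`` =
    100 * n_idt / n_d.
    """
    classes = ("helix", "sheet", "other")
    binders = {c.protein_residue for c in contacts}
    n_d = {cl: 0 for cl in classes}
    n_idt = {cl: 0 for cl in classes}
    for k in dot_residues:
        cl = ss.classes.get(k, "other")
        n_d[cl] += 1
        if k in binders:
            n_idt[cl] += 1
    rows = []
    for cl in classes:
        rows.append({"ss_class": cl, "n_idt": n_idt[cl], "n_d": n_d[cl],
                     "relative_binding_pct":
                         relative_percentage(n_idt[cl], n_d[cl], decimals)})
    df = pd.DataFrame(rows).set_index("ss_class")
    return df if df[["n_idt", "n_d"]].to_numpy().sum() else df.iloc[0:0]


def rna_ss_crosstab(contacts: Sequence[ContactRecord],
                    nt_classes: Mapping[ResidueKey, str],
                    dot_residues: Set[ResidueKey],
                    decimals: int = 2) -> pd.DataFrame:
    """Nucleotide-type × pairing-class contact preference for DOT residues.

    For each nucleotide type (A, C, G, U and an ``All`` margin) and pairing
    class (unpaired/basepaired/pseudoknot): ``n_idt`` distinct nucleotides
    contacting at least one DOT residue, ``n_prot`` distinct nucleotides
    contacting any residue, and the relative percentage. Zero rows are
    retained. A contacted nucleotide missing from ``nt_classes`` is an error.
    """
    pair_classes = ("unpaired", "basepaired", "pseudoknot")
    contacted: Dict[ResidueKey, bool] = {}
    for c in contacts:
        contacted[c.nucleotide] = contacted.get(c.nucleotide, False) or \
            (c.protein_residue in dot_residues)
    rows = []
    tallies: Dict[Tuple[str, str], List[int]] = {
        (nt, pc): [0, 0] for nt in NUCLEOTIDES for pc in pair_classes}
    for nt_key, touches_dot in contacted.items():
        if nt_key not in nt_classes:
            raise ValueError(f"contacted nucleotide {nt_key} has no secondary-structure annotation")
        cell = tallies.get((nt_key.res_name, nt_classes[nt_key]))
        if cell is None:
            continue
        cell[1] += 1
        if touches_dot:
            cell[0] += 1
    for nt in (*NUCLEOTIDES, "All"):
        for pc in pair_classes:
            if nt == "All":
                idt = sum(tallies[(x, pc)][0] for x in NUCLEOTIDES)
                prot = sum(tallies[(x, pc)][1] for x in NUCLEOTIDES)
            else:
                idt, prot = tallies[(nt, pc)]
            pct = relative_percentage(idt, prot, decimals)
            rows.append({"nucleotide": nt, "ss_class": pc, "n_idt": idt,
                         "n_prot": prot,
                         "relative_contact_pct": 0.0 if prot == 0 else pct})
    return pd.DataFrame(rows).set_index(["nucleotide", "ss_class"])


def nucleotide_contact_table(contacts: Sequence[ContactRecord],
                             dot_residues: Set[ResidueKey],
                             decimals: int = 1) -> pd.DataFrame:
    """Per nucleotide type: distinct nucleotides contacting DOT vs any residue."""
    contacted: Dict[ResidueKey, bool] = {}
    for c in contacts:
        contacted[c.nucleotide] = contacted.get(c.nucleotide, False) or \
            (c.protein_residue in dot_residues)
    rows = []
    for nt in NUCLEOTIDES:
        keys = [k for k in contacted if k.res_name == nt]
        idt = sum(1 for k in keys if contacted[k])
        prot = len(keys)
        rows.append({"nucleotide": nt, "n_idt": idt, "n_prot": prot,
                     "relative_contact_pct": relative_percentage(idt, prot, decimals)
                     if prot else 0.0})
    return pd.DataFrame(rows).set_index("nucleotide")
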