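"""End-to-end orchestration over a manifest of free/bound structure pairs.

The manifest is a TSV with columns ``complex_id``, ``free_pdb``,
``bound_pdb``, ``class`` (NR for non-ribosomal, RB for ribosomal) and
optional ``dotbracket`` (path to a two-line Vienna file: RNA sequence then
annotation, covering the complex's RNA chains in order) and ``dssp``
(path to a DSSP output file; otherwise the internal dihedral-basin
assigner is used).

For each dataset stratum and each distance cutoff the run emits TSV tables:
DOT regions, region count/length distributions, binding frequencies and
propensities with bootstrap standard errors, the DOT-vs-protein binding
comparison, the amino-acid × nucleotide contact matrix, protein and RNA
secondary-structure cross-tabulations, the nucleotide contact table, the
RASA comparison, and the pair-energy matrices — plus a run log recording
the configuration, seed, and per-complex warnings. A complex that fails
hard validation is skipped and logged; the run fails only if every complex
fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import dot_detection, features_energy, interface_stats, structure_io
from .dot_detection import DOTRegion, StructurePair
from .features_energy import EnergyParams
from .interface_stats import CountTable
from .structure_io import ResidueKey, Structure

logger = logging.getLogger("dotrna")

STRATA = ("NR", "RB")


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline run."""

    cutoffs: Tuple[float, ...] = (3.5, 6.0)
    bootstrap_n: int = 1000
    seed: int = 0
    dielectric: float = 1.0
    distance_dependent_dielectric: bool = False
    evaluation_shell: float = 10.0
    length_bins: Tuple[Tuple[int, Optional[int]], ...] = dot_detection.DEFAULT_LENGTH_BINS
    sasa_points: int = features_energy.DEFAULT_SPHERE_POINTS
    probe_radius: float = features_energy.DEFAULT_PROBE_RADIUS
    percent_decimals: int = 1
    energy_decimals: int = 2
    outdir: str = "dotrna_out"

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cutoffs) or list(self.cutoffs) != sorted(self.cutoffs):
            raise ValueError("cutoffs must be positive and sorted")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        if "length_bins" in raw:
            raw["length_bins"] = tuple((lo, hi) for lo, hi in raw["length_bins"])
        return cls(**raw)


@dataclass
class ComplexResult:
    """Per-complex intermediate results feeding the aggregate tables."""

    complex_id: str
    stratum: str
    pair: StructurePair
    dot_residues: set
    regions: List[DOTRegion]
    contacts: Dict[float, list]
    count_tables: Dict[float, CountTable]
    ss: structure_io.ProteinSS
    nt_classes: Dict[ResidueKey, str]
    rasa: Dict[ResidueKey, float]


def _read_vienna(path: str) -> Tuple[str, str]:
    lines = [l.strip() for l in Path(path).read_text().splitlines()
             if l.strip() and not l.startswith(">")]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected sequence and annotation lines")
    return lines[0], lines[1]


def _nt_classes_for(bound: Structure, dotbracket: Optional[Tuple[str, str]],
                    ) -> Dict[ResidueKey, str]:
    """Map each RNA residue to its pairing class from a dot-bracket annotation.

    The annotation covers the RNA chains concatenated in chain order. When
    no annotation is supplied every nucleotide is labelled unpaired, with a
    warning.
    """
    keys: List[ResidueKey] = []
    for chain in bound.chains("rna"):
        keys.extend(k for k in bound.chain_residues(chain, include_missing=False))
    if dotbracket is None:
        logger.warning("no dot-bracket annotation; labelling all nucleotides unpaired")
        return {k: "unpaired" for k in keys}
    seq, ann = dotbracket
    ss = structure_io.parse_dotbracket(seq, ann)
    if len(keys) != len(ss.classes):
        raise ValueError(f"dot-bracket length {len(ss.classes)} != "
                         f"{len(keys)} RNA residues")
    return dict(zip(keys, ss.classes))


def analyze_complex(complex_id: str, stratum: str, free_text: str, bound_text: str,
                    config: RunConfig,
                    dotbracket: Optional[Tuple[str, str]] = None,
                    dssp_text: Optional[str] = None) -> ComplexResult:
    """Run the full per-complex analysis chain."""
    free = structure_io.read_structure(free_text, name=f"{complex_id}:free")
    bound = structure_io.read_structure(bound_text, name=f"{complex_id}:bound")
    mapping = dot_detection.build_mapping(free, bound)
    pair = StructurePair(free=free, bound=bound, mapping=mapping)
    dot = dot_detection.find_dot_residues(pair)
    regions = dot_detection.segment_regions(dot)
    dot_in_regions = {k for r in regions for k in r.residues}

    contacts = {c: interface_stats.find_contacts(bound, c, dot_in_regions)
                for c in config.cutoffs}
    tables = {c: interface_stats.build_count_table(bound, dot_in_regions, contacts[c])
              for c in config.cutoffs}
    ss = (structure_io.read_protein_ss(dssp_text, bound) if dssp_text
          else structure_io.assign_ss_from_geometry(bound))
    nt_classes = _nt_classes_for(bound, dotbracket)

    prot_keys = bound.residues("protein")
    absolute = features_energy.compute_sasa(
        bound, probe_radius=config.probe_radius, n_points=config.sasa_points,
        keys=prot_keys)
    rasa = features_energy.relative_sasa(absolute)
    return ComplexResult(complex_id=complex_id, stratum=stratum, pair=pair,
                         dot_residues=dot_in_regions, regions=regions,
                         contacts=contacts, count_tables=tables, ss=ss,
                         nt_classes=nt_classes, rasa=rasa)


# ---------------------------------------------------------------------------
# aggregation and reporting

def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.6f")


def _region_table(results: Sequence[ComplexResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for reg in r.regions:
            rows.append({"complex_id": r.complex_id, "class": r.stratum,
                         "chain": reg.chain_id,
                         "start": f"{reg.start.seq_num}{reg.start.icode}",
                         "end": f"{reg.end.seq_num}{reg.end.icode}",
                         "length": reg.length})
    cols = ["complex_id", "class", "chain", "start", "end", "length"]
    return pd.DataFrame(rows, columns=cols).set_index("complex_id")


def _stat_table(tables: Sequence[CountTable], config: RunConfig, seed: int,
                ) -> pd.DataFrame:
    """Eq. 1/2/3 statistics with bootstrap SEs on one stratum × cutoff slice."""
    pooled = sum(tables[1:], tables[0])
    out = pooled.counts.copy()
    stats = {"freq_binding_in_dot": interface_stats.freq_binding_in_dot,
             "freq_dot_among_binders": interface_stats.freq_dot_among_binders,
             "propensity": interface_stats.propensity}
    for i, (name, fn) in enumerate(stats.items()):
        out[name] = fn(pooled)
        if len(tables) >= 2:
            res = interface_stats.bootstrap_stat(tables, fn, config.bootstrap_n,
                                                 seed=seed + i)
            out[name + "_se"] = res.se
        else:
            out[name + "_se"] = np.nan
    # DOT vs whole-protein binding comparison (per-type binding frequencies)
    out["freq_binding_protein"] = pooled.counts["n_ib"] / \
        pooled.counts["n_ip"].where(pooled.counts["n_ip"] > 0)
    return out


def run_pipeline(manifest: pd.DataFrame, config: RunConfig,
                 outdir: Optional[str] = None) -> Dict[str, pd.DataFrame]:
    """Execute the full analysis over a manifest and write the report bundle.

    Returns the report tables keyed by their file stem. Complexes failing
    validation are skipped with a log entry; an empty manifest or a manifest
    whose every complex fails raises ``ValueError``.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logged_cfg = {**asdict(config), "length_bins": list(map(list, config.length_bins))}
    logged_cfg.pop("outdir", None)  # not part of the scientific configuration
    run_log: Dict[str, object] = {"config": logged_cfg,
                                  "seed": config.seed, "complexes": {}}

    results: List[ComplexResult] = []
    for row in manifest.to_dict("records"):
        cid = str(row["complex_id"])
        try:
            dotbracket = None
            if row.get("dotbracket") and not pd.isna(row["dotbracket"]):
                dotbracket = _read_vienna(str(row["dotbracket"]))
            dssp_text = None
            if row.get("dssp") and not pd.isna(row["dssp"]):
                dssp_text = Path(str(row["dssp"])).read_text()
            stratum = str(row.get("class", "NR") or "NR")
            res = analyze_complex(cid, stratum,
                                  Path(str(row["free_pdb"])).read_text(),
                                  Path(str(row["bound_pdb"])).read_text(),
                                  config, dotbracket, dssp_text)
            results.append(res)
            run_log["complexes"][cid] = {"status": "ok",
                                         "n_regions": len(res.regions)}
        except Exception as exc:  # per-complex isolation
            logger.error("complex %s failed: %s", cid, exc)
            run_log["complexes"][cid] = {"status": "failed", "error": str(exc)}
    if not results:
        raise ValueError("all complexes failed validation")

    report: Dict[str, pd.DataFrame] = {}
    report["dot_regions"] = _region_table(results)

    strata: Dict[str, List[ComplexResult]] = {}
    for r in results:
        strata.setdefault(r.stratum, []).append(r)
    strata["ALL"] = results

    for stratum, group in sorted(strata.items()):
        summary = dot_detection.region_summary([r.regions for r in group],
                                               bins=config.length_bins)
        report[f"{stratum}_region_counts"] = pd.DataFrame(
            sorted(summary.regions_per_complex.items()),
            columns=["n_regions", "n_complexes"]).set_index("n_regions")
        report[f"{stratum}_region_lengths"] = pd.DataFrame(
            summary.length_histogram.items(),
            columns=["length_bin", "n_regions"]).set_index("length_bin")

        for cutoff in config.cutoffs:
            tag = f"{stratum}{cutoff:g}"
            tables = [r.count_tables[cutoff] for r in group]
            report[f"{tag}_stats"] = _stat_table(tables, config, config.seed)

            all_contacts = [c for r in group for c in r.contacts[cutoff]]
            report[f"{tag}_contact_matrix"] = interface_stats.aa_nt_contact_matrix(all_contacts)

            dot_all = set().union(*(r.dot_residues for r in group)) if group else set()
            ss_all = structure_io.ProteinSS(
                raw={k: v for r in group for k, v in r.ss.raw.items()},
                classes={k: v for r in group for k, v in r.ss.classes.items()})
            report[f"{tag}_protein_ss"] = interface_stats.protein_ss_crosstab(
                dot_all, all_contacts, ss_all, config.percent_decimals)

            nt_classes = {k: v for r in group for k, v in r.nt_classes.items()}
            report[f"{tag}_nucleotide_contacts"] = interface_stats.nucleotide_contact_table(
                all_contacts, dot_all, config.percent_decimals)
            report[f"{tag}_rna_ss"] = interface_stats.rna_ss_crosstab(
                all_contacts, nt_classes, dot_all)

    # RASA comparison and energies on the pooled dataset at the lower cutoff
    rasa_all = {(r.complex_id, k): v for r in results for k, v in r.rasa.items()}
    dot_tag = {(r.complex_id, k) for r in results for k in r.dot_residues}
    rasa_keyed = {ResidueKey(f"{c}/{k.chain_id}", k.seq_num, k.icode, k.res_name): v
                  for (c, k), v in rasa_all.items()}
    dot_keyed = {ResidueKey(f"{c}/{k.chain_id}", k.seq_num, k.icode, k.res_name)
                 for (c, k) in dot_tag}
    report["rasa_comparison"] = features_energy.rasa_comparison_table(rasa_keyed, dot_keyed)

    params = EnergyParams.default(dielectric=config.dielectric,
                                  distance_dependent_dielectric=config.distance_dependent_dielectric,
                                  evaluation_shell=config.evaluation_shell)
    base_cutoff = config.cutoffs[0]
    sums: Dict[bool, pd.DataFrame] = {}
    counts: Dict[bool, pd.DataFrame] = {}
    for r in results:
        em = features_energy.energy_matrix(r.pair.bound, r.contacts[base_cutoff],
                                           r.dot_residues, params, decimals=10)
        for stratum_flag, e, n in ((True, em.dot_energy, em.dot_count),
                                   (False, em.nondot_energy, em.nondot_count)):
            if stratum_flag not in sums:
                sums[stratum_flag] = e * 0.0
                counts[stratum_flag] = n * 0
            sums[stratum_flag] += e * n
            counts[stratum_flag] += n
    for flag, label in ((True, "dot"), (False, "nondot")):
        with np.errstate(invalid="ignore"):
            mean = (sums[flag] / counts[flag]).fillna(0.0) if flag in sums else None
        if mean is not None:
            report[f"energy_{label}"] = mean.map(
                lambda v: interface_stats.round_half_up(v, config.energy_decimals))
            report[f"energy_{label}_counts"] = counts[flag]

    for name, df in report.items():
        _write(df, out / f"{name}.tsv")
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    return report
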