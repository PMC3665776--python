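"""End-to-end orchestration: structure + alignment -> variation reports.

Runs the full comparative analysis from one reference structure with bound
ligands and one family alignment: binding residues (5 A rule), surface
residues (SASA, >20% rule), projection of both onto the family, per-group
charge-variation counts with the cross-group chi-square, per-member
binding-pocket size profiles, the selected-site summary and the
positive-selection enrichment test. Emits three TSV tables mirroring the
shapes of the published analysis plus a stats JSON and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .family_map import charge_class, column_map, read_alignment
from .pocket import core_binding_set, ligand_contact_residues, size_profile
from .stats import (
    charge_variation_table,
    chisq_independence,
    enrichment_test,
    selected_sites_summary,
)
from .structio import read_pdb
from .surface import shrake_rupley, surface_residues

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    pdb: str = ""
    alignment: str = ""
    reference_id: str = ""
    ligand_names: list[str] = field(default_factory=lambda: ["LIG"])
    cutoff: float = 5.0                 # A, ligand-contact rule
    surface_threshold: float = 0.20     # relative-accessibility rule
    first_residue_number: int = 1
    selected_sites: list[int] = field(default_factory=list)  # reference numbering
    last_helix_range: tuple[int, int] | None = None           # inclusive, reference numbering
    outdir: str = "cspstruct_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "last_helix_range" in raw and raw["last_helix_range"] is not None:
            raw["last_helix_range"] = tuple(raw["last_helix_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["last_helix_range"] is not None:
            d["last_helix_range"] = list(d["last_helix_range"])
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("read-structure")
def _load_structure(config: RunConfig):
    if not os.path.exists(config.pdb):
        raise FileNotFoundError(f"structure file not found: {config.pdb}")
    return read_pdb(config.pdb, ligand_names=set(config.ligand_names))


@_stage("read-alignment")
def _load_alignment(config: RunConfig):
    if not os.path.exists(config.alignment):
        raise FileNotFoundError(f"alignment file not found: {config.alignment}")
    return read_alignment(config.alignment)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes reports into ``config.outdir``.

    Returns a summary dict with the main statistics (also written to
    ``stats.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    structure = _load_structure(config)
    family = _load_alignment(config)

    try:
        cmap = column_map(family, config.reference_id, config.first_residue_number)
    except KeyError as exc:
        raise PipelineError("column-map", str(exc)) from exc

    # --- binding set and its core (5 A contact rule) ---
    try:
        binding = ligand_contact_residues(structure, config.ligand_names, cutoff=config.cutoff)
        number_of = {rid: rid[1] for rid in binding.members}
        cys = {rid for rid in binding.members
               if structure.residue_by_id(rid).aa == "C"}
        if config.last_helix_range is not None:
            lo, hi = config.last_helix_range
            helix = {rid for rid in binding.members if lo <= rid[1] <= hi} - cys
        else:
            helix = set()
        core = core_binding_set(binding, cys, helix)
        binding_numbers = sorted(number_of[rid] for rid in core.members)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("binding-set", str(exc)) from exc

    # --- surface set (>threshold relative accessibility) ---
    try:
        sasa = shrake_rupley(structure)
        surf = surface_residues(sasa, threshold=config.surface_threshold)
        surface_numbers = sorted(rid[1] for rid in surf.members)
        surface_cols = [cmap.column(n) for n in surface_numbers if n in cmap.number_to_column]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("surface", str(exc)) from exc

    # --- per-group charge variation over the surface columns ---
    try:
        groups = sorted(family.by_group())
        variation = charge_variation_table(family, {g: surface_cols for g in groups})
        chi2 = chisq_independence(variation.contingency()) if len(groups) >= 2 else None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("variation", str(exc)) from exc

    # --- size profiles over the core binding columns ---
    try:
        binding_cols = [cmap.column(n) for n in binding_numbers]
        profiles = []
        for rec in family.records:
            letters = [rec.sequence[c - 1] for c in binding_cols]
            prof = size_profile(letters, sequence_id=rec.id)
            profiles.append((rec, prof))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("size-profiles", str(exc)) from exc

    # --- selected sites: summary and enrichment among surface sites ---
    sites_rows = []
    enrichment = None
    if config.selected_sites:
        try:
            rel = {rid[1]: v for rid, v in
                   surface_residues(sasa, threshold=config.surface_threshold)
                   .relative_accessibility.items()}
            sites = [(f"site{n}", n) for n in config.selected_sites]
            sites_rows = selected_sites_summary(sites, family, cmap, [rel],
                                                binding_numbers)
            variable_col: dict[int, bool] = {}
            for col in surface_cols:
                letters = {r.sequence[col - 1] for r in family.records} - {"-", "X"}
                variable_col[col] = len({charge_class(l) for l in letters}) > 1
            selected_cols = {cmap.column(n) for n in config.selected_sites
                             if n in cmap.number_to_column}
            sel_surface = selected_cols & set(surface_cols)
            other_surface = set(surface_cols) - selected_cols
            if sel_surface and other_surface:
                enrichment = enrichment_test(sel_surface, other_surface, variable_col)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("selected-sites", str(exc)) from exc

    # --- reports ---
    pd.DataFrame(
        [{"group": r.group, "n_surface": r.n_surface, "n_variable": r.n_variable,
          "fraction": r.fraction, "percent": r.percent}
         for r in variation.rows.values()]
    ).to_csv(outdir / "table1.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"record": rec.id, "species": rec.species, "group": rec.group,
          "n_small": p.n_small, "n_intermediate": p.n_intermediate, "n_large": p.n_large}
         for rec, p in profiles]
    ).to_csv(outdir / "table2.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"site": r.site_label, "reference_number": r.reference_number,
          "mean_rel_acc": r.mean_rel_acc, "stdev_rel_acc": r.stdev_rel_acc,
          "single_model": r.single_model, "is_binding": r.is_binding,
          "variants": "".join(sorted(r.variants)),
          "has_charge_variation": r.has_charge_variation}
         for r in sites_rows]
    ).to_csv(outdir / "table3.tsv", sep="\t", index=False)

    stats_out = {
        "binding_residues": len(binding.members),
        "core_binding_residues": len(core.members),
        "surface_residues": len(surf.members),
        "charge_variation_chi2": None if chi2 is None else {
            "observed": chi2.observed, "statistic": chi2.statistic,
            "df": chi2.df, "p_value": chi2.p_value, "method": chi2.method},
        "enrichment": None if enrichment is None else {
            "observed": enrichment.observed, "p_value": enrichment.p_value,
            "method": enrichment.method},
    }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2)

    with open(outdir / "run.log", "w") as fh:
        fh.write(f"cspstruct {__version__} (python {sys.version.split()[0]})\n")
        fh.write(f"config: {json.dumps(config.to_dict(), sort_keys=True)}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"structure: {structure.id} ({len(structure.polymer_residues())} residues, "
                 f"{len(structure.ligands)} ligand(s))\n")
        fh.write(f"alignment: {len(family.records)} records x {family.alignment_length} columns\n")

    return stats_out
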