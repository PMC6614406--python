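"""One-shot analysis workflow and its configuration.

``run_pipeline`` executes any subset of the analysis stages against a local
coordinate file (and optional alignments/spectra), writes per-stage TSV/JSON
artifacts into the output directory and returns a single summary dictionary
keyed by quantity.  The configuration is a flat YAML file; explicit keyword
overrides (e.g. from command-line flags) take precedence over file values,
which take precedence over defaults.  Nothing is ever downloaded: the
deposited entry to analyse must be fetched by the user beforehand.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import contacts as cts
from . import spectra as spc
from . import substitutions as subs
from .geometry import bridge_conformations, ring_plane_angles
from .structure_io import (CellParams, LigandTable, Structure,
                           extract_chromophores, parse_structure)


def _spacegroup_multiplicity(hm: str) -> int:
    import gemmi
    sg = gemmi.find_spacegroup_by_name(hm)
    if sg is None:
        raise ValueError(f"unknown space group {hm!r}")
    return len(sg.operations())

logger = logging.getLogger(__name__)

ALL_STAGES = ("census", "geometry", "distances", "interface", "solvent",
              "contacts", "substitutions", "deconvolve")


@dataclass
class RunConfig:
    """Effective settings of one pipeline run; every field has a default."""

    structure_path: str | None = None
    ligand_codes: tuple[str, ...] = ("CYC",)
    ligand_table_path: str | None = None

    # surface / interface
    probe_radius: float = 1.4
    sasa_points: int = 960
    include_ligands: bool = True

    # distances
    center_mode: str = "conjugated"
    distance_cap: float = 51.0
    contact_cutoff: float = 4.5

    # contacts
    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 4.5

    # substitutions
    alignment_paths: dict = field(default_factory=dict)   # subunit -> path
    alignment_format: str = "fasta"
    query_ids: dict = field(default_factory=dict)         # subunit -> id
    chain_assignment: dict = field(default_factory=dict)  # subunit -> [chains]
    conservation_threshold: float = 0.9
    pair_cutoff: float = 6.0

    # solvent content
    cell_params: dict | None = None   # a/b/c/alpha/beta/gamma/space_group
    asu_mass_da: float | None = None
    asu_sequences: dict = field(default_factory=dict)     # label -> [seq, copies]
    asu_ligands: dict | None = None                       # code -> count (None: census)

    # spectra
    spectrum_path: str | None = None
    reference_centers: tuple[float, ...] | None = None
    n_components: int | str = "auto"
    fit_window: tuple[float, float] = (450.0, 750.0)
    restarts: int = 20

    seed: int = 0
    output_dir: str = "phycostruct_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, tuple):
                out[k] = list(v)
        return out


def _ligand_table(config: RunConfig) -> LigandTable:
    if config.ligand_table_path:
        return LigandTable.from_file(config.ligand_table_path)
    return LigandTable()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the requested stages and return the summary dictionary.

    Artifacts (per-stage TSV/JSON plus ``summary.json`` and the echoed
    effective config) are written under ``config.output_dir``.
    """
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.as_dict()))

    structural = {"census", "geometry", "distances", "interface", "contacts"}
    need_structure = structural & set(stages) or (
        "substitutions" in stages and config.chain_assignment)
    structure = chroms = amap = None
    table = _ligand_table(config)
    if need_structure:
        if not config.structure_path:
            missing = sorted(structural & set(stages))
            raise StageError(missing[0] if missing else "substitutions",
                             "structure_path is required but not set")
        structure = parse_structure(config.structure_path)
        chroms = extract_chromophores(structure, config.ligand_codes, table)
        complete = [c for c in chroms if c.is_complete]
        if {"distances", "interface", "geometry", "contacts"} & set(stages):
            amap = asm.build_assembly_map(structure, chroms, config.contact_cutoff)

    summary: dict = {}

    if "census" in stages:
        summary["census"] = asm.census(structure)
        (outdir / "census.json").write_text(json.dumps(summary["census"], indent=2))

    if "geometry" in stages:
        rows = []
        for c in complete:
            rep = ring_plane_angles(c)
            conf = bridge_conformations(c, table)
            rows.append({"chromophore": c.key, "site_class": c.site_class,
                         "angle_AB": rep.angle_AB, "angle_BC": rep.angle_BC,
                         "angle_CD": rep.angle_CD, "conformation": conf.summary})
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "geometry.tsv", sep="\t", index=False)
        geo: dict = {"n_chromophores": len(rows)}
        for site in asm.SITE_CLASSES:
            vals = df.loc[df.site_class == site, "angle_BC"].dropna()
            if len(vals):
                geo[f"angle_BC_mean_{site}"] = float(vals.mean())
                geo[f"angle_BC_sd_{site}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        geo["conformations"] = sorted(set(df.conformation)) if len(df) else []
        summary["geometry"] = geo

    if "distances" in stages:
        dt = asm.distance_table(structure, amap, complete,
                                mode=config.center_mode, cap=config.distance_cap)
        asm.format_distance_table(dt, config.distance_cap).to_csv(
            outdir / "distance_table.tsv", sep="\t")
        summary["distance_table"] = {
            level: {col: (None if np.isnan(v) else ("exceeds_cap" if np.isinf(v)
                                                    else round(float(v), 3)))
                    for col, v in row.items()}
            for level, row in dt.iterrows()}

    if "interface" in stages:
        if not amap.monomers:
            raise StageError("interface", "no alpha-beta monomer found")
        a, b = amap.monomers[0]
        rep = asm.buried_area(structure, {a}, {b},
                              include_ligands=config.include_ligands,
                              probe_radius=config.probe_radius,
                              n_points=config.sasa_points)
        summary["interface"] = rep.as_dict()
        (outdir / "interface.json").write_text(json.dumps(rep.as_dict(), indent=2))

    if "solvent" in stages:
        if config.cell_params is not None:
            p = dict(config.cell_params)
            sg = p.pop("space_group", "P 1")
            cell = CellParams(**p, space_group=sg,
                              z_asu_per_cell=_spacegroup_multiplicity(sg))
        else:
            if structure is None and config.structure_path:
                structure = parse_structure(config.structure_path)
            cell = structure.cell if structure is not None else None
        if cell is None:
            raise StageError("solvent", "no unit cell in structure or config")
        mass = config.asu_mass_da
        if mass is None and config.asu_sequences:
            ligs = config.asu_ligands
            if ligs is None:
                ligs = asm.census(structure)["ligand_residues"]
            mass = asm.asu_mass_from_sequences(
                {k: (v[0], int(v[1])) for k, v in config.asu_sequences.items()},
                ligs)
        if mass is None:
            raise StageError("solvent", "need asu_mass_da or asu_sequences")
        summary["solvent_content"] = asm.solvent_content(cell, mass).as_dict()

    if "contacts" in stages:
        rows = []
        for c in complete:
            for h in cts.hydrogen_bonds(c, structure, config.hbond_cutoff, table):
                rows.append({"chromophore": c.key, "site_class": c.site_class,
                             "residue": h.partner_label, "atom": h.partner_atom,
                             "type": f"hbond_{h.classification}",
                             "distance": round(h.distance, 3)})
            for rc in cts.binding_pocket(c, structure, config.hydrophobic_cutoff,
                                         config.hbond_cutoff, table):
                rows.append({"chromophore": c.key, "site_class": c.site_class,
                             "residue": rc.label, "atom": "",
                             "type": f"pocket_{rc.contact_type}",
                             "distance": round(rc.min_distance, 3)})
        pd.DataFrame(rows).to_csv(outdir / "contacts.tsv", sep="\t", index=False)
        summary["contacts"] = {"n_records": len(rows)}

    if "substitutions" in stages:
        if not config.alignment_paths:
            raise StageError("substitutions", "no alignment_paths configured")
        records = []
        for subunit, apath in sorted(config.alignment_paths.items()):
            aln = subs.read_alignment(apath, config.alignment_format)
            qid = config.query_ids.get(subunit)
            if qid is None:
                raise StageError("substitutions",
                                 f"no query id configured for subunit {subunit!r}")
            records.extend(subs.find_substitutions(
                aln, qid, config.conservation_threshold, subunit=subunit))
        sub_rows = [{"subunit": r.subunit, "position": r.position,
                     "conserved": r.conserved_residue, "query": r.query_residue,
                     "conservation": round(r.conservation, 3)} for r in records]
        pd.DataFrame(sub_rows).to_csv(outdir / "substitutions.tsv",
                                      sep="\t", index=False)
        sub_summary: dict = {
            "n_substitutions": len(records),
            "per_subunit": {s: sum(1 for r in records if r.subunit == s)
                            for s in sorted({r.subunit for r in records})},
        }
        if structure is not None and config.chain_assignment:
            mapped = subs.map_to_structure(records, structure,
                                           config.chain_assignment)
            if amap is None:
                amap = asm.build_assembly_map(structure, chroms,
                                              config.contact_cutoff)
            pairs = subs.compensatory_pairs(mapped, structure, amap,
                                            d_max=config.pair_cutoff)
            sub_summary["compensatory_pairs"] = [
                {"a": p.record_a.label, "b": p.record_b.label,
                 "distance": round(p.min_distance, 2),
                 "net_volume_change": round(p.net_volume_change, 1),
                 "evidence": p.evidence} for p in pairs]
            (outdir / "compensatory_pairs.json").write_text(
                json.dumps(sub_summary["compensatory_pairs"], indent=2))
        summary["substitutions"] = sub_summary

    if "deconvolve" in stages:
        if not config.spectrum_path:
            raise StageError("deconvolve", "spectrum_path is required but not set")
        spectrum = spc.read_spectrum(config.spectrum_path)
        model = spc.fit_gaussians(spectrum, n_components=config.n_components,
                                  fit_window=tuple(config.fit_window),
                                  restarts=config.restarts, seed=config.seed)
        comp_rows = []
        total_area = sum(model.component_areas())
        for comp, area in zip(model.components, model.component_areas()):
            comp_rows.append({"center_nm": round(comp.center, 2),
                              "width_nm": round(comp.width, 2),
                              "amplitude": round(comp.amplitude, 4),
                              "area_percent": round(100.0 * area / total_area, 1)})
        pd.DataFrame(comp_rows).to_csv(outdir / "spectral_components.tsv",
                                       sep="\t", index=False)
        fitted = pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                               "absorbance": spectrum.absorbance,
                               "fitted": model.predict(spectrum.wavelengths)})
        fitted.to_csv(outdir / "fitted_spectrum.csv", index=False)
        dec = {"n_components": len(model.components),
               "centers_nm": [round(c, 2) for c in model.centers],
               "rss": model.rss, "bic": model.bic, "aicc": model.aicc}
        if config.reference_centers is not None:
            ref = sorted(config.reference_centers)
            if len(ref) == len(model.components):
                dec["shifts_vs_reference_nm"] = [
                    round(c - r, 2) for c, r in zip(model.centers, ref)]
        summary["deconvolve"] = dec

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
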