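"""Directory-level orchestration: screen a folder of genomes, run a
configured simulation, write reproducible reports with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._io import GenomeIOError, read_genome
from .biofilm import (SimGrid, SimResult, SimulationConfig, StrainParams,
                      make_founder_layout, merged_rgb, simulate)
from .genomes import SyntheticGenome, translate
from .operon import assign_pherotype, classify_comP, extract_comQXPA
from .rapp import detect_rapP_module
from .references import ReferenceSet, default_references

log = logging.getLogger("quorumcomp")

FASTA_EXTS = (".fasta", ".fa", ".fna")
GFF_EXTS = (".gff3", ".gff")


class ConfigSchemaError(ValueError):
    """Simulation config missing or mistyping a required field."""


@dataclass
class RunManifest:
    tool_version: str
    seed: int | None
    config_hash: str | None = None
    input_checksums: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pair_genome_files(input_dir: Path) -> tuple[list[tuple[Path, Path]], list[Path]]:
    by_stem: dict[str, dict[str, Path]] = {}
    for p in sorted(input_dir.iterdir()):
        if p.suffix in FASTA_EXTS:
            by_stem.setdefault(p.stem, {})["fasta"] = p
        elif p.suffix in GFF_EXTS:
            by_stem.setdefault(p.stem, {})["gff"] = p
    pairs, unpaired = [], []
    for stem in sorted(by_stem):
        d = by_stem[stem]
        if "fasta" in d and "gff" in d:
            pairs.append((d["fasta"], d["gff"]))
        else:
            unpaired.extend(d.values())
    return pairs, unpaired


def screen_genome(genome: SyntheticGenome,
                  refs: ReferenceSet | None = None) -> dict:
    """One merged per-genome report row (comP + pherotype + rapP calls)."""
    refs = refs or default_references()
    operon = extract_comQXPA(genome, refs)
    comp = classify_comP(operon, refs)
    comq = operon.gene_seqs.get("comQ", "")
    pherotype = assign_pherotype(translate(comq), refs) if comq else None
    rapp = detect_rapP_module(genome, refs)
    return {
        "genome_id": genome.genome_id,
        "operon_complete": operon.complete,
        "operon_flags": ";".join(operon.completeness),
        "comP_status": comp.status,
        "comP_classes": ";".join(sorted(comp.classes)),
        "comP_predicted_length_aa": comp.predicted_length_aa,
        "comP_runs_off": comp.runs_off,
        "comP_identity": round(comp.identity, 2),
        "hotspot_present": comp.hotspot.present,
        "hotspot_run_length": comp.hotspot.run_length,
        "hotspot_indel_in_run": comp.hotspot.indel_in_run,
        "pherotype": pherotype.label if pherotype else "undetermined",
        "pherotype_identity": round(pherotype.identity, 2) if pherotype else 0.0,
        "rapP_presence": rapp.presence,
        "rapP_residue_236": rapp.residue_236,
        "rapP_phrP_downstream": rapp.phrP_downstream,
        "rapP_replicon": rapp.replicon,
        "rapP_identity": round(rapp.identity, 2),
    }


def summarise_screen(report: pd.DataFrame) -> dict:
    """Census-style counts over a per-genome report table."""
    if report.empty:
        return {"n_genomes": 0}
    n = len(report)
    disrupted = report["comP_status"] == "disrupted"
    classes = report.loc[disrupted, "comP_classes"].str.split(";").explode()
    rapp_present = report["rapP_presence"] != "absent"
    return {
        "n_genomes": int(n),
        "comP_intact": int((report["comP_status"] == "intact").sum()),
        "comP_disrupted": int(disrupted.sum()),
        "comP_undetermined": int((report["comP_status"] == "undetermined").sum()),
        "comP_disrupted_percent": round(100.0 * float(disrupted.sum()) / n, 1),
        "comP_classes": classes.value_counts().to_dict(),
        "hotspot_indel_genomes": int(report["hotspot_indel_in_run"].sum()),
        "rapP_complete": int((report["rapP_presence"] == "complete").sum()),
        "rapP_five_prime_truncated":
            int((report["rapP_presence"] == "five_prime_truncated").sum()),
        "rapP_absent": int((report["rapP_presence"] == "absent").sum()),
        "rapP_N236T_unresponsive":
            int((report.loc[rapp_present, "rapP_residue_236"] == "T").sum()),
        "rapP_on_plasmid":
            int((report.loc[rapp_present, "rapP_replicon"] == "plasmid_like").sum()),
        "rapP_chromosomal":
            int((report.loc[rapp_present, "rapP_replicon"] == "chromosomal").sum()),
    }


def run_screen(input_dir: str | Path, out_dir: str | Path,
               refs: ReferenceSet | None = None) -> tuple[pd.DataFrame, dict]:
    """Screen every paired FASTA/GFF3 genome in a directory.

    Unpaired files are listed and skipped with a warning; a corrupt genome is
    skipped without aborting the rest; an empty directory yields an empty
    report. Writes screen_report.tsv, screen_report.json and a manifest.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = refs or default_references()

    pairs, unpaired = _pair_genome_files(input_dir)
    for p in unpaired:
        log.warning("unpaired input skipped: %s", p)
    if not pairs:
        log.warning("no paired FASTA/GFF3 genomes found in %s", input_dir)

    rows, checksums = [], {}
    for fasta, gff in pairs:
        try:
            genome = read_genome(fasta, gff)
            rows.append(screen_genome(genome, refs))
            checksums[fasta.name] = _sha256(fasta)
            checksums[gff.name] = _sha256(gff)
        except (GenomeIOError, ValueError) as e:
            log.warning("skipping %s: %s", fasta.stem, e)

    report = pd.DataFrame(rows)
    summary = summarise_screen(report)
    report.to_csv(out_dir / "screen_report.tsv", sep="\t", index=False)
    (out_dir / "screen_report.json").write_text(
        json.dumps({"summary": summary,
                    "genomes": rows}, indent=2, default=str) + "\n")
    RunManifest(__version__, None, None, checksums,
                datetime.now(timezone.utc).isoformat()
                ).write(out_dir / "manifest.json")
    return report, summary


_REQUIRED_SIM_FIELDS = {
    "grid": ("nx", "radius"),
    "strains": (),
    "layout": ("n_per_strain", "inoculum_radius", "spot_radius", "b0", "seed"),
}


def load_sim_config(config_path: str | Path) -> SimulationConfig:
    """Parse and validate a YAML simulation config; schema violations are
    reported (naming the field) before any compute."""
    raw = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(raw, dict):
        raise ConfigSchemaError("config must be a mapping")
    for section, fields in _REQUIRED_SIM_FIELDS.items():
        if section not in raw:
            raise ConfigSchemaError(f"missing required field: {section}")
        for f in fields:
            if f not in raw[section]:
                raise ConfigSchemaError(f"missing required field: {section}.{f}")
    strains = raw["strains"]
    if not (isinstance(strains, list) and len(strains) == 2):
        raise ConfigSchemaError("strains must list exactly two strains")
    for i, s in enumerate(strains):
        for f in ("name", "r", "d"):
            if f not in s:
                raise ConfigSchemaError(f"missing required field: strains[{i}].{f}")

    grid = SimGrid.disc(radius=float(raw["grid"]["radius"]),
                        nx=int(raw["grid"]["nx"]))
    lay = raw["layout"]
    layout = make_founder_layout(int(lay["n_per_strain"]),
                                 float(lay["inoculum_radius"]),
                                 float(lay["spot_radius"]), float(lay["b0"]),
                                 int(lay["seed"]), grid=grid)
    return SimulationConfig(
        grid=grid,
        strains=(StrainParams(strains[0]["name"], float(strains[0]["r"]),
                              float(strains[0]["d"])),
                 StrainParams(strains[1]["name"], float(strains[1]["r"]),
                              float(strains[1]["d"]))),
        layout=layout,
        dt=raw.get("dt"),
        t_end=float(raw.get("t_end", 50.0)),
        coverage_stop=float(raw.get("coverage_stop", 0.90)),
        occupancy_threshold=float(raw.get("occupancy_threshold", 0.05)),
        snapshot_every=raw.get("snapshot_every"),
    )


def run_simulation(config_path: str | Path, out_dir: str | Path) -> SimResult:
    """Run one configured simulation; write outcome TSV, per-channel 16-bit
    TIFF snapshots of the final state, a merged pseudo-colour PNG, and the
    run manifest."""
    import imageio.v3 as iio
    import tifffile

    config_path, out_dir = Path(config_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = load_sim_config(config_path)
    result = simulate(config)

    o = result.outcome
    pd.DataFrame([{
        "f1": o.f1, "f2": o.f2,
        "percent_challenger_remaining": o.percent_challenger_remaining,
        "area_fraction_1": o.area_fraction[0],
        "area_fraction_2": o.area_fraction[1],
        "t_final": result.state.t,
    }]).to_csv(out_dir / "outcome.tsv", sep="\t", index=False)

    full = np.iinfo(np.uint16).max
    for name, B in (("B1", result.state.B1), ("B2", result.state.B2)):
        tifffile.imwrite(out_dir / f"final_{name}.tiff",
                         np.clip(B * full, 0, full).astype(np.uint16))
    iio.imwrite(out_dir / "final_merged.png",
                merged_rgb(result.state.B1, result.state.B2))

    RunManifest(__version__, config.layout.seed, _sha256(config_path),
                {config_path.name: _sha256(config_path)},
                datetime.now(timezone.utc).isoformat()
                ).write(out_dir / "manifest.json")
    return result
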