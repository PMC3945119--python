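"""End-to-end pipeline driver: simulate -> preprocess -> segment -> extract
-> qc -> profile -> dp -> map, with one seeded config and a hashed manifest.

Every stage writes its outputs under the run directory and records them in
a JSON manifest with SHA-256 content hashes; identical config + seed gives
identical hashes.  Stage seeds are derived from the master seed so stages
are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, mapping, profiling, qc, segmentation, synthdata
from .errors import PlastError

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable parameters for a full run (defaults = printed pipeline
    values where available)."""

    seed: int = 0
    out_dir: str = "plast_run"
    # simulate
    simulate: bool = True
    n_strains: int = 12
    cells_per_strain: int = 20
    image_size: tuple = (256, 256)
    n_cells_per_field: int = 5
    pattern_classes: tuple = ("nuclear", "cytoplasmic", "punctate")
    channel_offset: tuple = (0, 0)
    # preprocess
    ball_radius: int = 50
    dic_sigma: float = 25.0
    max_shift: int = 20
    # segmentation
    nucleus_window: int = 35
    nucleus_bias: float = -60.0
    theta_area: float = 2000.0
    theta_dna: float = 1000.0
    # qc
    min_area: int = 300
    max_area: int = 2000
    max_solidity_metric: float = 0.2
    # profiling
    profile_method: str = "mean"
    # mapping
    alpha_adj: float = 2.5e-4
    log_level: str = "INFO"

    KNOWN = None  # set after class creation

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise PlastError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("image_size", "channel_offset", "pattern_classes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}, "files": {}}
    rng = np.random.default_rng(config.seed)
    stage_seed = {s: int(rng.integers(2**31 - 1)) for s in
                  ("simulate", "segment", "profile", "map")}

    def record(stage, path):
        path = Path(path)
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(str(path.relative_to(out)))

    if not config.simulate:
        raise PlastError("stage simulate: disabled and no input images configured")

    # --- simulate + preprocess + segment + extract, one field per strain ---
    params = segmentation.SegmentationParams(
        nucleus_window=config.nucleus_window,
        nucleus_bias=config.nucleus_bias,
        theta_area=config.theta_area,
        theta_dna=config.theta_dna,
    )
    tables = []
    sim_rng = np.random.default_rng(stage_seed["simulate"])
    from .features import LocalStructureParams, extract_field_features

    ls_params = LocalStructureParams()
    for i in range(config.n_strains):
        strain = f"S{i:04d}"
        pattern = config.pattern_classes[i % len(config.pattern_classes)]
        strain_dir = out / "fields" / strain
        rows = []
        n_fields = max(1, int(np.ceil(config.cells_per_strain / config.n_cells_per_field)))
        for f in range(n_fields):
            spec = synthdata.SyntheticFieldSpec(
                image_size=tuple(config.image_size),
                n_cells=config.n_cells_per_field,
                pattern_class=pattern,
                channel_offset=tuple(config.channel_offset),
                seed=int(sim_rng.integers(2**31 - 1)),
            )
            fieldi, truth = synthdata.generate_field(spec)
            paths = synthdata.write_field_bundle(fieldi, truth, spec, strain_dir / f"f{f}")
            for p in paths.values():
                record("simulate", p)
            record("simulate", strain_dir / f"f{f}" / "spec.json")

            gfp = imaging.subtract_background_fluorescence(fieldi.gfp, config.ball_radius)
            dna = imaging.subtract_background_fluorescence(fieldi.dna, config.ball_radius)
            dic = imaging.subtract_background_dic(fieldi.dic, config.dic_sigma)
            if config.channel_offset != (0, 0):
                dy, dx = imaging.align_channels(fieldi.dic, fieldi.gfp, max_shift=config.max_shift)
                dic = imaging.apply_shift(dic, (dy, dx), fill=1.0)

            nuclei = segmentation.detect_nuclei(dna, params)
            cells = segmentation.segment_cells(dic, nuclei, params)
            cells = segmentation.combine_cells(cells, dna, config.theta_area, config.theta_dna)
            import tifffile

            mask_path = strain_dir / f"f{f}" / "cell_mask.tif"
            tifffile.imwrite(mask_path, cells.labels.astype(np.uint16))
            record("segment", mask_path)
            tab = extract_field_features(gfp, cells, nuclei, strain, ls_params)
            tab["cell_id"] = tab["cell_id"] + f"_f{f}"
            rows.append(tab)
        tables.append(pd.concat(rows, ignore_index=True))

    features_path = out / "features.tsv"
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(features_path, sep="\t", index=False)
    record("extract", features_path)

    # --- qc ---
    policy = qc.QCPolicy(
        min_area=config.min_area,
        max_area=config.max_area,
        max_solidity_metric=config.max_solidity_metric,
    )
    table_qc, log = qc.run_qc(table, policy)
    qc_path = out / "features_qc.tsv"
    table_qc.to_csv(qc_path, sep="\t", index=False)
    log.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    record("qc", qc_path)
    record("qc", out / "qc_report.tsv")

    # --- profiles + dp ---
    if table_qc["strain_id"].nunique() < 2:
        raise PlastError("stage profile: fewer than two strains survive QC")
    profiles = profiling.build_profiles(table_qc, method=config.profile_method)
    prof_df = pd.DataFrame(
        [{"strain_id": p.strain_id, "method": p.method, **dict(zip(p.feature_names, p.weights))} for p in profiles]
    )
    prof_path = out / "profiles.tsv"
    prof_df.to_csv(prof_path, sep="\t", index=False)
    record("profile", prof_path)

    dmat = profiling.dp_matrix(profiles)
    dp_path = out / "dp_matrix.tsv"
    dmat.to_csv(dp_path, sep="\t")
    record("dp", dp_path)

    # --- map against a catalog of pattern-class compartments plus
    # per-strain singleton landmarks (so each protein scores >= 10
    # compartments even in small demo runs) ---
    strains = sorted(dmat.index)
    comps = {}
    for s in strains:
        cls = config.pattern_classes[int(s[1:]) % len(config.pattern_classes)]
        comps.setdefault(f"class_{cls}", set()).add(s)
        comps[f"strain_{s}"] = {s}
    catalog = mapping.CompartmentCatalog(comps)
    dp_comp = mapping.dp_to_compartments(dmat, catalog)
    locmap = mapping.build_localization_map(dp_comp)
    mapping.assign_compartments(locmap, config.alpha_adj)
    map_path = out / "localization_map.csv"
    locmap.z.to_csv(map_path)
    record("map", map_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
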