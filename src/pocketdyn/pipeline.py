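"""End-to-end orchestration: site resolution -> superposition -> RMSD stats ->
clustering -> per-member pocket grids -> transient regions -> conservation.

A run is configured by a :class:`RunConfig` (JSON-serializable; every
parameter the workflow exposes has a config key with its standard default) and
produces a directory of CSV/DX/JSON artifacts plus a ``run.log`` echoing the
seed and all parameters, so webserver-style sessions are reproducible from a
single file.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .binding_site import (BindingSiteDefinition, define_site_from_ligand,
                           define_site_from_point, map_site_residues)
from .cluster import (DEFAULT_SEED, DEFAULT_SINGLE_LINKAGE_THRESHOLD,
                      ClusteringResult, cluster_report, kmeans_threshold_cluster,
                      single_linkage_cluster)
from .conservation import (conservation_profile, differential_conservation,
                           map_scores_to_structure)
from .io_formats import (MSA, Structure, StructureEnsemble, read_msa_fasta,
                         read_pdb, write_dx_grid, write_multimodel_pdb, write_pdb)
from .pocket_grid import (DEFAULT_CONTACT_DISTANCE, DEFAULT_MIN_BURIED,
                          DEFAULT_PROBE_RADIUS, DEFAULT_SCAN_DEPTH,
                          DEFAULT_SPACING, PocketGrid, build_grid, detect_pocket,
                          lining_residue_comparison, pocket_stats)
from .superpose import (per_residue_rmsd_stats, residue_feature_centers,
                        site_rmsd, superpose_member)
from .transient_pockets import (DEFAULT_CONSERVED_FRACTION,
                                DEFAULT_MIN_SUBPOCKET_POINTS, DEFAULT_THRESHOLDS,
                                frequency_grid, opening_series, transient_regions)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "summarize"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run (paths may be None when
    the corresponding stage is driven from in-memory objects or skipped)."""

    # inputs
    ensemble_paths: List[str] = field(default_factory=list)
    reference_path: Optional[str] = None
    ligand_path: Optional[str] = None
    site_center: Optional[Tuple[float, float, float]] = None
    msa_path: Optional[str] = None
    off_target_id: Optional[str] = None
    model_policy: str = "all"
    # binding site
    site_radius: float = 5.0
    mapping_min_identity: float = 0.2
    # RMSD / clustering
    rmsd_metric: str = "backbone"  # or "sidechain_center"
    cluster_method: str = "single_linkage"  # or "kmeans"
    cluster_threshold: float = DEFAULT_SINGLE_LINKAGE_THRESHOLD
    kmeans_max_k: Optional[int] = None
    seed: int = DEFAULT_SEED
    # pocket grid
    grid_spacing: float = DEFAULT_SPACING
    grid_margin: float = 2.0
    probe_radius: float = DEFAULT_PROBE_RADIUS
    min_buried_directions: int = DEFAULT_MIN_BURIED
    scan_depth: float = DEFAULT_SCAN_DEPTH
    contact_distance: float = DEFAULT_CONTACT_DISTANCE
    # transient regions
    transient_thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS
    conserved_fraction: float = DEFAULT_CONSERVED_FRACTION
    min_subpocket_points: int = DEFAULT_MIN_SUBPOCKET_POINTS
    include_reference_in_frequency: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        cfg.transient_thresholds = tuple(cfg.transient_thresholds)
        if cfg.site_center is not None:
            cfg.site_center = tuple(cfg.site_center)
        return cfg


@dataclass
class PipelineResult:
    out_dir: Path
    site: BindingSiteDefinition
    clustering: ClusteringResult
    rmsd_matrix: np.ndarray
    pocket_volumes: List[float]
    n_subpockets: int
    summary: Dict


def _load_ensemble(config: RunConfig) -> StructureEnsemble:
    if config.reference_path is None:
        raise ValueError("config.reference_path is required")
    reference = read_pdb(config.reference_path, model_policy="first")[0]
    members: List[Structure] = []
    labels: List[str] = []
    for p in config.ensemble_paths:
        for struct in read_pdb(p, model_policy=config.model_policy):
            members.append(struct)
            labels.append(struct.id)
    if not members:
        raise ValueError("no ensemble members given")
    return StructureEnsemble(reference=reference, members=members, source_labels=labels)


def _resolve_site(config: RunConfig, reference: Structure) -> BindingSiteDefinition:
    if config.ligand_path is not None:
        ligand = read_pdb(config.ligand_path, model_policy="first")[0]
        return define_site_from_ligand(reference, ligand, config.site_radius)
    if config.site_center is not None:
        return define_site_from_point(reference, config.site_center, config.site_radius)
    raise ValueError("config must give either ligand_path or site_center")


ALL_STAGES = frozenset({"analysis", "pocket", "conservation"})


def run_pipeline(config: RunConfig, out_dir,
                 ensemble: Optional[StructureEnsemble] = None,
                 site: Optional[BindingSiteDefinition] = None,
                 msa: Optional[MSA] = None,
                 stages: frozenset = ALL_STAGES) -> PipelineResult:
    """Execute the full analysis on an ensemble and write all artifacts.

    ``ensemble``, ``site`` and ``msa`` may be passed directly (bypassing the
    config's input paths), which is how the synthetic-fixture commands and the
    test-bed drive the pipeline. ``stages`` restricts the run: superposition,
    RMSD statistics and clustering always execute; ``"pocket"`` adds grid
    detection and transient regions, ``"conservation"`` adds MSA scoring.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pocketdyn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("pocketdyn %s | python %s", __version__, sys.version.split()[0])
        log.info("parameters: %s", json.dumps(asdict(config), default=str))
        config.to_json(out / "config.json")

        if ensemble is None:
            ensemble = _load_ensemble(config)
        if site is None:
            site = _resolve_site(config, ensemble.reference)
        log.info("binding site: %d residues within %.2f A (source=%s)",
                 len(site.residue_keys), site.radius, site.source)
        pd.DataFrame(
            [{"chain_id": k.chain_id, "res_seq": k.res_seq,
              "insertion_code": k.insertion_code, "res_name": k.res_name}
             for k in site.residue_keys]
        ).to_csv(out / "site_residues.csv", index=False)

        # --- superposition ---------------------------------------------------
        mappings = []
        fitted: List[Structure] = []
        fit_rmsds = []
        for member in ensemble.members:
            mapping = map_site_residues(site, ensemble.reference, member,
                                        min_identity=config.mapping_min_identity)
            fit, rmsd = superpose_member(member, ensemble.reference, site, mapping)
            mappings.append(mapping)
            fitted.append(fit)
            fit_rmsds.append(rmsd)
        ensemble = StructureEnsemble(reference=ensemble.reference, members=fitted,
                                     source_labels=ensemble.source_labels)
        write_multimodel_pdb([ensemble.reference] + fitted, out / "superposed.pdb")
        log.info("superposed %d members (fit RMSD %.3f-%.3f A)",
                 len(fitted), min(fit_rmsds), max(fit_rmsds))

        # --- RMSD statistics --------------------------------------------------
        matrix, per_member_mean, per_residue_max = per_residue_rmsd_stats(
            ensemble, site, mappings, metric=config.rmsd_metric)
        labels = ensemble.source_labels
        pd.DataFrame(matrix, index=labels, columns=labels).to_csv(out / "rmsd_matrix.csv")
        pd.DataFrame({"member": labels, "fit_rmsd": fit_rmsds,
                      "mean_site_rmsd": per_member_mean}).to_csv(
            out / "per_member_mean.csv", index=False)
        pd.DataFrame(
            [{"residue": str(site.residue_keys[i]), "max_rmsd": per_residue_max[k.ident]}
             for i, k in enumerate(site.residue_keys)]
        ).to_csv(out / "per_residue_max.csv", index=False)

        # --- clustering -------------------------------------------------------
        ref_rmsds = np.array([
            site_rmsd(m, ensemble.reference, site, mp, metric=config.rmsd_metric)
            for m, mp in zip(ensemble.members, mappings)
        ])
        if config.cluster_method == "single_linkage":
            clustering = single_linkage_cluster(matrix, config.cluster_threshold)
        elif config.cluster_method == "kmeans":
            features = _sidechain_center_features(ensemble, site, mappings)
            clustering = kmeans_threshold_cluster(
                features, config.cluster_threshold, seed=config.seed,
                max_k=config.kmeans_max_k,
                n_residues=len(site.residue_keys))
        else:
            raise ValueError(f"unknown cluster method {config.cluster_method!r}")
        report = cluster_report(clustering, matrix, member_labels=labels,
                                rmsd_to_reference=ref_rmsds)
        report.to_csv(out / "cluster_report.csv", index=False)
        pd.DataFrame({
            "member": labels,
            "label": clustering.labels,
            "is_representative": [i in clustering.representatives
                                  for i in range(len(labels))],
        }).to_csv(out / "clusters.csv", index=False)
        log.info("%s clustering at %.2f A: %d clusters",
                 clustering.method, clustering.threshold, clustering.n_clusters)

        # --- pocket detection -------------------------------------------------
        ref_stats = None
        member_stats = []
        sub_rows: List[Dict] = []
        n_subpockets = 0
        if "pocket" not in stages:
            return _finish(out, ensemble, site, clustering, matrix, labels,
                           ref_stats, member_stats, sub_rows, n_subpockets,
                           None)
        grid = build_grid(site, margin=config.grid_margin, spacing=config.grid_spacing)
        ref_pocket = detect_pocket(ensemble.reference, grid, site,
                                   probe_radius=config.probe_radius,
                                   min_buried_directions=config.min_buried_directions,
                                   scan_depth=config.scan_depth)
        member_pockets: List[PocketGrid] = [
            detect_pocket(m, grid, site, probe_radius=config.probe_radius,
                          min_buried_directions=config.min_buried_directions,
                          scan_depth=config.scan_depth)
            for m in ensemble.members
        ]
        ref_stats = pocket_stats(ref_pocket, ensemble.reference,
                                 config.contact_distance, config.probe_radius)
        member_stats = [pocket_stats(p, m, config.contact_distance, config.probe_radius)
                        for p, m in zip(member_pockets, ensemble.members)]
        stats_rows = []
        for st in [ref_stats] + member_stats:
            row = {"structure": st.structure_id, "volume": st.volume,
                   "surface_area": st.surface_area,
                   "n_lining_residues": len(st.lining_residues)}
            row.update({f"n_{k}": v for k, v in st.property_counts.items()})
            stats_rows.append(row)
        pd.DataFrame(stats_rows).to_csv(out / "pocket_stats.csv", index=False)
        lining_residue_comparison(member_stats, ref_stats).to_csv(
            out / "lining_residues.csv", index=False)
        write_dx_grid(ref_pocket.grid.like(ref_pocket.grid.values.astype(float)),
                      out / "pocket_reference.dx")

        # --- transient regions ------------------------------------------------
        pockets_for_freq = list(member_pockets)
        if config.include_reference_in_frequency:
            pockets_for_freq = [ref_pocket] + pockets_for_freq
        freq = frequency_grid(pockets_for_freq)
        write_dx_grid(freq.grid, out / "frequency.dx")
        series_rows = []
        for thr in config.transient_thresholds:
            regions = transient_regions(freq, ref_pocket, thr,
                                        conserved_fraction=config.conserved_fraction,
                                        min_subpocket_points=config.min_subpocket_points)
            tag = f"{int(round(thr * 100))}"
            write_dx_grid(regions.appearing.like(regions.appearing.values.astype(float)),
                          out / f"appearing_{tag}.dx")
            write_dx_grid(regions.disappearing.like(regions.disappearing.values.astype(float)),
                          out / f"disappearing_{tag}.dx")
            if thr == config.transient_thresholds[0]:
                write_dx_grid(regions.conserved.like(regions.conserved.values.astype(float)),
                              out / "conserved.dx")
            for sp in regions.subpockets:
                n_subpockets += 1
                sub_rows.append({
                    "threshold": thr, "region": sp.region, "label": sp.label,
                    "n_points": sp.size,
                    "volume": sp.size * grid.spacing ** 3,
                    "centroid_x": sp.centroid[0], "centroid_y": sp.centroid[1],
                    "centroid_z": sp.centroid[2],
                })
                series = opening_series(sp, member_pockets)
                for m, frac in enumerate(series):
                    series_rows.append({
                        "threshold": thr, "region": sp.region, "label": sp.label,
                        "member": labels[m], "open_fraction": float(frac),
                        "open_volume": float(frac) * sp.size * grid.spacing ** 3,
                    })
        pd.DataFrame(sub_rows).to_csv(out / "subpockets.csv", index=False)
        pd.DataFrame(series_rows).to_csv(out / "opening_series.csv", index=False)
        log.info("transient analysis: %d sub-pockets across thresholds %s",
                 n_subpockets, config.transient_thresholds)

        # --- conservation (optional) -------------------------------------------
        conservation_summary = None
        if msa is None and config.msa_path is not None and "conservation" in stages:
            msa = read_msa_fasta(config.msa_path)
        if msa is not None and "conservation" in stages:
            if config.off_target_id is not None:
                off_row = msa.row(config.off_target_id)
                on_msa = msa.without(config.off_target_id)
                profile = differential_conservation(on_msa, off_row,
                                                    off_id=config.off_target_id)
                scoring_msa = on_msa
            else:
                profile = conservation_profile(msa)
                scoring_msa = msa
            residue_scores = map_scores_to_structure(profile, scoring_msa,
                                                     ensemble.reference)
            res_by_col = profile.column_to_residue
            pd.DataFrame([
                {"column": j,
                 "raw": profile.column_scores_raw[j],
                 "rescaled": profile.column_scores_rescaled[j],
                 "residue": str(_key_for(ensemble.reference, res_by_col[j]))
                            if j in res_by_col else ""}
                for j in range(profile.width)
            ]).to_csv(out / "conservation.csv", index=False)
            write_pdb(ensemble.reference, out / "reference_conservation.pdb",
                      b_factors=residue_scores)
            site_scores = {str(k): residue_scores[k.ident]
                           for k in site.residue_keys if k.ident in residue_scores}
            top = sorted(site_scores.items(), key=lambda kv: -kv[1])[:10]
            conservation_summary = {"mode": profile.mode,
                                    "top_site_residues": top}
            log.info("conservation (%s mode): %d columns scored, %d residues mapped",
                     profile.mode, profile.width, len(residue_scores))

        return _finish(out, ensemble, site, clustering, matrix, labels,
                       ref_stats, member_stats, sub_rows, n_subpockets,
                       conservation_summary)
    finally:
        root.removeHandler(handler)
        handler.close()


def _finish(out, ensemble, site, clustering, matrix, labels,
            ref_stats, member_stats, sub_rows, n_subpockets,
            conservation_summary) -> PipelineResult:
    summary = {
        "n_members": len(ensemble.members),
        "n_site_residues": len(site.residue_keys),
        "cluster_method": clustering.method,
        "n_clusters": clustering.n_clusters,
        "representatives": [labels[i] for i in clustering.representatives],
        "reference_pocket_volume": ref_stats.volume if ref_stats else None,
        "member_pocket_volumes": {
            lab: st.volume for lab, st in zip(labels, member_stats)},
        "n_subpockets": n_subpockets,
        "subpockets": sub_rows,
        "conservation": conservation_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return PipelineResult(
        out_dir=out, site=site, clustering=clustering, rmsd_matrix=matrix,
        pocket_volumes=[st.volume for st in member_stats],
        n_subpockets=n_subpockets, summary=summary,
    )


def _key_for(structure: Structure, ident):
    for k in structure.residues:
        if k.ident == ident:
            return k
    return ident


def _sidechain_center_features(ensemble: StructureEnsemble,
                               site: BindingSiteDefinition,
                               mappings) -> np.ndarray:
    """Concatenated per-residue side-chain centers, member x (3*R).

    Residues unmapped in some member take that member's site centroid as a
    neutral placeholder so the feature matrix stays rectangular.
    """
    features = []
    for member, mapping in zip(ensemble.members, mappings):
        mapped = mapping.mapped()
        keys = [mapped.get(k.ident) for k in site.residue_keys]
        centers = residue_feature_centers(member, [k for k in keys if k is not None])
        fallback = np.mean([c for c in centers.values()], axis=0)
        row = []
        for k in keys:
            row.append(centers.get(k.ident, fallback) if k is not None else fallback)
        features.append(np.concatenate(row))
    return np.array(features)


def summarize(run_dir) -> Dict:
    """Reload the machine-readable summary of a finished run directory."""
    path = Path(run_dir) / "summary.json"
    if not path.exists():
        raise FileNotFoundError(f"{path}: no summary found; did the run finish?")
    return json.loads(path.read_text())
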