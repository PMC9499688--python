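"""End-to-end analysis pipeline.

Chains every analysis on a trajectory and writes the full figure-data set
as TSV tables, each headed by a provenance block (package version, config
hash, input hash, seed). Ligand analyses are skipped with a logged notice
when no ligand chains are present. The pipeline is a pure function of
(input file, config): identical inputs give byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import AnalysisConfig
from .core import Trajectory, select
from .ensembles import (
    convergence_check,
    daura_cluster,
    pairwise_rmsd_matrix,
    pdf_1d,
    pmf_2d,
    project_clusters,
)
from .geometry import end_to_end_distance, kabsch_superpose, radius_of_gyration
from .interactions import (
    chpi_min_distance,
    hbond_count_pdf,
    interpeptide_contact_map,
    ligand_binding_probability,
    ligand_hbond_profile,
    stacking_events,
)
from .structure_metrics import (
    assign_secondary_structure,
    shrake_rupley_sasa,
    ss_population,
)

logger = logging.getLogger(__name__)

__all__ = ["run_full_pipeline"]


def _fmt(x) -> str:
    if isinstance(x, float):
        return "nan" if np.isnan(x) else f"{x:.6g}"
    return str(x)


class _Bundle:
    def __init__(self, out_dir: Path, header: list[str]):
        self.out_dir = out_dir
        self.header = header
        out_dir.mkdir(parents=True, exist_ok=True)

    def write(self, name: str, columns: list[str], rows) -> Path:
        path = self.out_dir / name
        with open(path, "w") as fh:
            for line in self.header:
                fh.write(f"# {line}\n")
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
        return path


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def run_full_pipeline(traj: Trajectory, config: AnalysisConfig,
                      out_dir, input_hash: str = "in-memory") -> dict:
    """Run every analysis stage on a trajectory and emit the TSV bundle.

    Returns a dict of computed headline quantities (secondary-structure
    populations, cluster census, stacking summary, ...) for programmatic
    use; the TSV files carry the full tables.
    """
    out_dir = Path(out_dir)
    header = [
        f"oligolens {__version__}",
        f"config {config.provenance_hash()}",
        f"input {input_hash}",
        f"seed {config.seed}",
    ]
    bundle = _Bundle(out_dir, header)
    top = traj.topology
    results: dict = {}

    # ---- secondary structure (populations overall and per residue)
    ss = assign_secondary_structure(traj)
    pops = ss_population(ss)
    bundle.write("ss_populations.tsv", ["category", "fraction", "stderr"],
                 [(c, f, e) for c, (f, e) in pops.items()])
    per_res = ss_population(ss, per_residue=True)
    bundle.write("ss_per_residue.tsv", list(per_res.columns),
                 per_res.itertuples(index=False))
    results["ss_populations"] = {c: f for c, (f, _) in pops.items()}

    # ---- RMSD vs frame 0, end-to-end, H-bond PDFs
    ca = select(top, "peptide and name CA")
    coords = traj.coords()[:, ca, :]
    ref = coords[0]
    rmsd_ts = np.array([kabsch_superpose(ref, c).rmsd for c in coords])
    bundle.write("rmsd_timeseries.tsv", ["frame", "rmsd_nm"],
                 enumerate(rmsd_ts.tolist()))
    rmsd_pdf = pdf_1d(rmsd_ts)
    bundle.write("rmsd_pdf.tsv", ["rmsd_nm", "density"],
                 zip(rmsd_pdf.centers, rmsd_pdf.densities))
    ree = []
    for frame in traj.frames:
        for chain in top.peptide_chains():
            ree.append(end_to_end_distance(
                [top.residues[ri] for ri in chain.residues], top, frame))
    ree_pdf = pdf_1d(np.asarray(ree))
    bundle.write("end_to_end_pdf.tsv", ["distance_nm", "density"],
                 zip(ree_pdf.centers, ree_pdf.densities))
    hb_kwargs = dict(distance_cutoff=config.hbond_distance_cutoff,
                     angle_cutoff=config.hbond_angle_cutoff)
    for cls in ("MC", "SC"):
        dist = hbond_count_pdf(traj, hb_class=cls, **hb_kwargs)
        bundle.write(f"hbond_count_pdf_{cls.lower()}.tsv",
                     ["count", "probability"], sorted(dist.items()))
        results[f"hbond_pdf_{cls}"] = dist
    results["rmsd_mean"] = float(rmsd_ts.mean())
    results["end_to_end_mean"] = float(np.mean(ree))

    # ---- SASA–RG free-energy landscape + clustering
    pep_atoms = select(top, "peptide")
    masses = top.masses()[pep_atoms]
    sasa_vals = np.empty(traj.n_frames)
    rg_vals = np.empty(traj.n_frames)
    for fi, frame in enumerate(traj.frames):
        sasa_vals[fi] = shrake_rupley_sasa(
            frame, top, probe=config.sasa_probe, n_points=config.sasa_points,
            atom_indices=pep_atoms).total
        rg_vals[fi] = radius_of_gyration(frame.coordinates[pep_atoms], masses)
    surface = pmf_2d(sasa_vals, rg_vals, temperature=config.temperature,
                     bins=config.pmf_bins)
    xc = 0.5 * (surface.x_edges[:-1] + surface.x_edges[1:])
    yc = 0.5 * (surface.y_edges[:-1] + surface.y_edges[1:])
    rows = []
    for i, xv in enumerate(xc):
        for j, yv in enumerate(yc):
            f = surface.free_energy[i, j]
            rows.append((xv, yv, "NA" if np.isnan(f) else f"{f:.6g}"))
    bundle.write("pmf_sasa_rg.tsv",
                 ["sasa_nm2", "rg_nm", "free_energy_kcal_mol"], rows)
    dm = pairwise_rmsd_matrix(traj, ca)
    clusters = daura_cluster(traj, ca, cutoff=config.cluster_cutoff,
                             rmsd_matrix=dm)
    proj = project_clusters(clusters, sasa_vals, rg_vals,
                            top_k=config.top_k_clusters)
    bundle.write("clusters_top.tsv",
                 ["rank", "medoid_frame", "sasa_nm2", "rg_nm", "fraction"],
                 [(k + 1, m, x, y, fr)
                  for k, (m, x, y, fr) in enumerate(proj)])
    member_rows = []
    for cid, (medoid, members) in enumerate(clusters.clusters):
        for fidx in members:
            member_rows.append((fidx, cid, int(fidx == medoid)))
    member_rows.sort()
    bundle.write("cluster_assignments.tsv",
                 ["frame", "cluster_id", "is_medoid"], member_rows)
    results["n_clusters"] = clusters.n_clusters
    results["top_cluster_fractions"] = [p[3] for p in proj]
    results["sasa_mean"] = float(sasa_vals.mean())
    results["rg_mean"] = float(rg_vals.mean())

    # ---- inter-peptide contact maps
    for cls in ("MC-MC", "SC-SC"):
        cmap = interpeptide_contact_map(traj, contact_class=cls,
                                        cutoff=config.contact_cutoff)
        rows = [(cmap.labels[i], cmap.labels[j], cls,
                 cmap.probabilities[i, j])
                for i in range(len(cmap.labels))
                for j in range(len(cmap.labels))]
        bundle.write(f"contact_map_{cls.lower().replace('-', '_')}.tsv",
                     ["res_i", "res_j", "class", "probability"], rows)
        results[f"contact_map_{cls}"] = cmap.probabilities

    # ---- ligand analyses (soft-skipped without ligands)
    if top.ligand_chains():
        labels, binding = ligand_binding_probability(
            traj, cutoff=config.contact_cutoff)
        bundle.write("ligand_binding_probability.tsv",
                     ["residue", "probability"], zip(labels, binding))
        labels, mc, sc = ligand_hbond_profile(traj, **hb_kwargs)
        bundle.write("ligand_hbond_profile.tsv",
                     ["residue", "mc_hbonds", "sc_hbonds"],
                     zip(labels, mc, sc))
        results["binding_probability"] = dict(zip(labels, binding))
        results["ligand_hbond_mc"] = dict(zip(labels, mc))

        def phe_rings(res):
            return res.name == "PHE" and bool(res.rings)

        def ligand_benzene(res):
            # first ring of the ligand template is the benzene ring
            return res.name == "MEL" and bool(res.rings)

        lig_rings = [(ri, 0) for ri, res in enumerate(top.residues)
                     if res.name == "MEL" and res.rings]
        phe_ring_sel = [(ri, 0) for ri, res in enumerate(top.residues)
                        if res.name == "PHE" and res.rings]
        if phe_ring_sel and lig_rings:
            events = stacking_events(
                traj, phe_ring_sel, lig_rings,
                parallel_max=config.stacking_parallel_max,
                herringbone_min=config.stacking_herringbone_min)
            bundle.write("stacking_events.tsv",
                         ["frame", "res_a", "res_b", "distance_nm",
                          "angle_deg", "class"],
                         [(e.frame, e.ring_a[0], e.ring_b[0],
                           e.centroid_distance, e.angle, e.classification)
                          for e in events])
            if events:
                ang = np.array([e.angle for e in events])
                dst = np.array([e.centroid_distance for e in events])
                stack_pmf = pmf_2d(ang, dst,
                                   temperature=config.temperature,
                                   bins=(30, 30))
                xa = 0.5 * (stack_pmf.x_edges[:-1] + stack_pmf.x_edges[1:])
                yd = 0.5 * (stack_pmf.y_edges[:-1] + stack_pmf.y_edges[1:])
                rows = []
                for i, xv in enumerate(xa):
                    for j, yv in enumerate(yd):
                        f = stack_pmf.free_energy[i, j]
                        rows.append((xv, yv,
                                     "NA" if np.isnan(f) else f"{f:.6g}"))
                bundle.write("stacking_pmf.tsv",
                             ["angle_deg", "distance_nm",
                              "free_energy_kcal_mol"], rows)
                results["stacking_modal_angle"] = float(
                    ang[np.argmin(np.abs(ang - np.median(ang)))])
                results["stacking_median_distance"] = float(np.median(dst))
        # CH-pi: Ile/Leu methyls vs ligand benzene rings
        for resname in ("ILE", "LEU"):
            sel = [ri for ri, res in enumerate(top.residues)
                   if res.name == resname and res.methyls]
            if not sel or not lig_rings:
                continue
            d = chpi_min_distance(traj, sel, lig_rings)
            cp = pdf_1d(d)
            bundle.write(f"chpi_pdf_{resname.lower()}_ligand.tsv",
                         ["distance_nm", "density"],
                         zip(cp.centers, cp.densities))
            results[f"chpi_{resname}_median"] = float(np.median(d))
        # F23-F23 ring-pair distance PDF
        if len(phe_ring_sel) >= 2:
            ev = stacking_events(traj, phe_ring_sel, phe_ring_sel)
            dst = np.array([e.centroid_distance for e in ev])
            pp = pdf_1d(dst)
            bundle.write("phe_phe_distance_pdf.tsv",
                         ["distance_nm", "density"],
                         zip(pp.centers, pp.densities))
    else:
        logger.info("no ligand chains: ligand analyses skipped")

    # ---- per-residue coil/beta probabilities (headline per-residue view)
    results["per_residue_beta"] = dict(
        zip(per_res["label"], per_res["beta_sheet"]))
    results["per_residue_coil"] = dict(zip(per_res["label"], per_res["coil"]))

    # ---- convergence
    if config.window_a is not None and config.window_b is not None:
        report = convergence_check(
            traj, slice(*config.window_a), slice(*config.window_b),
            threshold=config.convergence_threshold)
        bundle.write("convergence.tsv", ["observable", "jsd_bits"],
                     [(k, v) for k, v in report.items()
                      if k not in ("threshold", "converged")]
                     + [("threshold", report["threshold"]),
                        ("converged", int(report["converged"]))])
        results["convergence"] = report
    return results
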