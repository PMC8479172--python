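"""Configuration-driven orchestration of the full analysis.

A run goes: inputs (files or synthetic specs) → H-bond detection and
binding-state classification → core alignment and comparative geometry →
interaction energetics → PCA/cross-correlation → residue network → report.
Bound-frame masks from the classifier feed every "bound frames only"
analysis.  All stage outputs are TSV/JSON; a report manifest with content
hashes makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dynamics, energetics, geometry, hbonds, network, synthetic
from .hbonds import BindingState
from .trajectory_io import DomainLabel, Ensemble, SelectionExpr

__all__ = ["RunConfig", "RunReport", "run", "load_config", "default_config"]

_KNOWN_KEYS = {
    "seed", "out_dir", "equilibration_ns", "persistence_ns",
    "network_threshold", "k_paths", "conditions", "core_residues",
    "latch_pairs", "path_sources", "path_sinks", "pin_residues",
    "energy_stride", "hinge_mobile", "hinge_candidates",
    "interface_residues",
}

_PRESETS = {"tight": synthetic.nat_like_spec, "loose": synthetic.nas_like_spec}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    equilibration_ns: float = 5.0
    persistence_ns: float = 5.0
    network_threshold: float = 0.7
    k_paths: int = 100
    # condition name -> {"preset": tight|loose, **SyntheticSpec overrides}
    conditions: dict[str, dict] = field(default_factory=dict)
    core_residues: list[list[int]] = field(default_factory=lambda: [[5, 55]])
    latch_pairs: list = field(default_factory=lambda: [
        [[106, "CA"], [90, "CA"]], [[28, "CA"], [90, "CA"]],
    ])
    path_sources: list[int] = field(default_factory=lambda: [62, 64, 65])
    path_sinks: list[int] = field(default_factory=lambda: [28])
    pin_residues: list[int] = field(default_factory=lambda: [106])
    energy_stride: int = 10
    hinge_mobile: list[list[int]] = field(default_factory=lambda: [[66, 100]])
    hinge_candidates: list[int] = field(default_factory=list)
    # the declared domain interface: hinge candidates come from the
    # low-RMSD quartile of these residues
    interface_residues: list[list[int]] = field(
        default_factory=lambda: [[56, 70]])

    @staticmethod
    def from_dict(data: Mapping[str, Any]) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return RunConfig(**data)


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)   # name -> status
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256
    parameters: dict[str, Any] = field(default_factory=dict)
    warnings_seen: list[str] = field(default_factory=list)
    summary: dict[str, Any] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def default_config(seed: int = 0, n_replicas: int = 2,
                   n_frames: int = 800) -> RunConfig:
    """Two-condition synthetic benchmark: tight vs loose binding."""
    return RunConfig(
        seed=seed,
        conditions={
            "TIGHT": {"preset": "tight", "n_replicas": n_replicas,
                      "n_frames": n_frames},
            "LOOSE": {"preset": "loose", "n_replicas": n_replicas,
                      "n_frames": n_frames},
        },
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_condition(name: str, cfg: Mapping[str, Any], seed: int,
                    seed_offset: int = 0):
    """Instantiate a synthetic condition from its preset + overrides."""
    cfg = dict(cfg)
    preset = cfg.pop("preset", "tight")
    if preset not in _PRESETS:
        raise ValueError(f"condition {name}: unknown preset {preset!r}")
    spec = _PRESETS[preset](seed=seed + seed_offset, condition=name, **cfg)
    # the allosteric block: mobile-domain latch + pin + static-domain latch
    rho = 0.9 if preset == "tight" else 0.5
    block = synthetic.CorrBlock(
        atoms=tuple((rid, "CA") for rid in (62, 64, 65, 106, 28, 29)),
        target_correlation=rho,
    )
    spec.corr_blocks = spec.corr_blocks + (block,)
    return spec


def run(config: RunConfig,
        write_outputs: bool = True) -> tuple[RunReport, dict]:
    """Execute every stage in dependency order; abort on the first error.

    Returns the report and the in-memory stage state (ensembles, traces,
    averages, models, networks) for callers that continue programmatically.
    """
    report = RunReport(parameters={
        "seed": config.seed,
        "equilibration_ns": config.equilibration_ns,
        "persistence_ns": config.persistence_ns,
        "network_threshold": config.network_threshold,
        "k_paths": config.k_paths,
    })
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            state = _run_stages(config, report, out, write_outputs)
        except Exception as exc:
            stage = report.stages.get("_current", "unknown")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        finally:
            report.stages.pop("_current", None)
            report.warnings_seen = sorted(
                {str(w.message) for w in caught}
            )

    if write_outputs:
        report_path = out / "report.json"
        report_path.write_text(json.dumps({
            "stages": report.stages,
            "parameters": report.parameters,
            "summary": report.summary,
            "warnings": report.warnings_seen,
            "manifest": report.manifest,
        }, indent=2, default=str))
    return report, state


def _run_stages(config: RunConfig, report: RunReport, out: Path,
                write_outputs: bool) -> dict:
    state: dict[str, Any] = {}

    # --- simulate ---------------------------------------------------------
    report.stages["_current"] = "simulate"
    ensembles: dict[str, Ensemble] = {}
    truths = {}
    for k, (name, cfg) in enumerate(sorted(config.conditions.items())):
        spec = build_condition(name, cfg, config.seed, seed_offset=1000 * k)
        ens, truth = synthetic.simulate(spec)
        ensembles[name] = ens
        truths[name] = truth
        state.setdefault("specs", {})[name] = spec
    state["ensembles"] = ensembles
    state["truths"] = truths
    report.stages["simulate"] = "ok"

    top = next(iter(ensembles.values())).topology
    first = sorted(ensembles)[0]

    # --- hbonds + binding -------------------------------------------------
    report.stages["_current"] = "hbonds"
    bond_specs = {}
    occ_rows = []
    traces = {}
    for name, ens in ensembles.items():
        spec = state["specs"][name]
        specs = [
            hbonds.HBondSpec.from_names(top, hb.label, hb.donor, hb.hydrogen,
                                        hb.acceptors, hb.group)
            for hb in spec.hbonds
        ]
        bond_specs[name] = specs
        traces[name] = [hbonds.detect_hbonds(t, specs) for t in ens]
    state["traces"] = traces
    report.stages["hbonds"] = "ok"

    report.stages["_current"] = "bind"
    bound_masks = {}
    states_all = {}
    for name, ens in ensembles.items():
        spec = state["specs"][name]
        ga = [hb.label for hb in spec.hbonds if hb.group == "A"]
        gb = [hb.label for hb in spec.hbonds if hb.group == "B"]
        eq = hbonds.equilibration_mask(
            ens.trajectories[0].n_frames, ens.trajectories[0].dt,
            config.equilibration_ns,
        )
        masks = []
        cond_states = []
        for trace in traces[name]:
            bt = hbonds.classify_binding(trace, ga, gb,
                                         config.persistence_ns)
            cond_states.append(bt)
            masks.append(eq & (bt.states == int(BindingState.FULLY_BOUND)))
        bound_masks[name] = masks
        states_all[name] = cond_states
        prob = hbonds.hbond_probability(traces[name], masks)
        for lab, (m, s) in prob.items():
            occ_rows.append({"condition": name, "bond": lab,
                             "mean": m, "sd": s})
        joint_a = hbonds.joint_occupancy(traces[name], ga, "all_present", masks)
        report.summary[f"joint_groupA_{name}"] = joint_a
    state["bound_masks"] = bound_masks
    state["binding_states"] = states_all
    occ_df = pd.DataFrame(occ_rows)
    if write_outputs:
        _write_tsv(occ_df, out / "hbond_occupancy.tsv")
    state["occupancy"] = occ_df
    report.stages["bind"] = "ok"

    # --- geometry ---------------------------------------------------------
    report.stages["_current"] = "geometry"
    core_expr = SelectionExpr(
        residue_ranges=tuple(tuple(r) for r in config.core_residues),
        atom_names=("CA",),
    )
    core_ids = core_expr.resolve(top)
    core_rows = top.indices_of(core_ids)
    reference = ensembles[first].trajectories[0].coords[0]
    aligned: dict[str, list] = {}
    for name, ens in ensembles.items():
        aligned[name] = [
            geometry.align_trajectory(t, core_rows, reference) for t in ens
        ]
    state["aligned"] = aligned

    averages = {}
    for name in ensembles:
        averages[name] = geometry.average_structure(
            Ensemble(aligned[name]), bound_masks[name],
            mask_note="bound frames, post-equilibration",
        )
    state["averages"] = averages

    names = sorted(ensembles)
    if len(names) >= 2:
        a, b = names[0], names[1]
        blocks = {
            "TM": [r for r in top.residue_ids()
                   if top.atom(top.residues[r][0]).domain_label == DomainLabel.TM],
            "PP": [r for r in top.residue_ids()
                   if top.atom(top.residues[r][0]).domain_label == DomainLabel.PP],
        }
        ddmap = geometry.distance_difference_map(
            Ensemble(aligned[b]), Ensemble(aligned[a]),
            mask_a=bound_masks[b], mask_b=bound_masks[a], blocks=blocks,
        )
        state["ddmap"] = ddmap
        block_df = pd.DataFrame(
            [{"block_a": ka, "block_b": kb, "mean_delta": v}
             for (ka, kb), v in ddmap.block_means.items()]
        )
        if write_outputs:
            _write_tsv(block_df, out / "distance_difference_blocks.tsv")

        mobile = [r for lo, hi in config.hinge_mobile for r in range(lo, hi + 1)]
        interface = [r for lo, hi in config.interface_residues
                     for r in range(lo, hi + 1) if r in top.residues]
        candidates = config.hinge_candidates or geometry.low_rmsd_candidates(
            averages[a], averages[b], pool=interface,
        )
        hinge = geometry.hinge_scan(averages[a], averages[b],
                                    candidates, mobile)
        state["hinge"] = hinge
        if write_outputs:
            _write_tsv(
                pd.DataFrame(hinge.ranked, columns=["residue", "pearson_r"]),
                out / "hinge_scan.tsv",
            )
        report.summary["hinge_best"] = hinge.ranked[0][0]
        report.summary["hinge_best_r"] = hinge.ranked[0][1]

    hist_rows = []
    bins = np.arange(0.0, 120.0, 0.5)
    aligned_ens = {n: Ensemble(aligned[n]) for n in ensembles}
    for pair in config.latch_pairs:
        p = (tuple(pair[0]), tuple(pair[1]))
        hists = geometry.latch_distance_histograms(
            aligned_ens, p, bins,
            masks={n: bound_masks[n] for n in ensembles},
        )
        for cond, h in hists.items():
            hist_rows.append({
                "pair": f"{p[0][0]}{p[0][1]}-{p[1][0]}{p[1][1]}",
                "condition": cond, "mode": h["mode"], "sd": h["sd"],
                "tail_fraction": h["tail_fraction"],
            })
        state.setdefault("latch_hists", {})[p] = hists
    latch_df = pd.DataFrame(hist_rows)
    if write_outputs:
        _write_tsv(latch_df, out / "latch_histograms.tsv")
    state["latch_summary"] = latch_df
    report.stages["geometry"] = "ok"

    # --- energetics -------------------------------------------------------
    report.stages["_current"] = "energy"
    pep_ids = SelectionExpr(domain_labels=(DomainLabel.PEPTIDE,)).resolve(top)
    prot_ids = SelectionExpr(
        domain_labels=(DomainLabel.TM, DomainLabel.PP)
    ).resolve(top)
    decomps = {}
    for name, ens in ensembles.items():
        per_frame_totals = []
        decomp = None
        for traj, mask in zip(ens, bound_masks[name]):
            strided = mask.copy()
            keep = np.nonzero(strided)[0][::config.energy_stride]
            strided[:] = False
            strided[keep] = True
            if not strided.any():
                continue
            d = energetics.interaction_energy(traj, pep_ids, prot_ids,
                                              frame_mask=strided)
            per_frame_totals.append(d.total)
            decomp = d  # keep last replica's table; totals pooled below
        decomps[name] = decomp
        if per_frame_totals:
            pooled = np.concatenate(per_frame_totals)
            report.summary[f"interaction_energy_mean_{name}"] = float(pooled.mean())
            means = [float(x.mean()) for x in per_frame_totals]
            if len(means) >= 3:
                sd_jk, sd_ref, ratio = energetics.jackknife_check(
                    means, pooled)
                report.summary[f"jackknife_ratio_{name}"] = ratio
    state["energy"] = decomps
    if len(names) >= 2 and decomps[names[0]] is not None and decomps[names[1]] is not None:
        diff = energetics.per_residue_difference(
            decomps[names[0]], decomps[names[1]], threshold=0.0)
        if write_outputs:
            _write_tsv(diff, out / "energy_per_residue_difference.tsv")
        state["energy_diff"] = diff
    report.stages["energy"] = "ok"

    # --- pca / correlations -----------------------------------------------
    report.stages["_current"] = "pca"
    prot_ca = SelectionExpr(
        domain_labels=(DomainLabel.TM, DomainLabel.PP), atom_names=("CA",)
    ).resolve(top)
    ca_rows = top.indices_of(prot_ca)
    ca_rids = [top.atom(i).residue_id for i in prot_ca]
    coords_by_cond = {
        n: [t.coords[:, ca_rows] for t in aligned[n]] for n in ensembles
    }
    combined = [c for n in names for c in coords_by_cond[n]]
    combined_masks = [m for n in names for m in bound_masks[n]]
    model, projections = dynamics.cartesian_pca(
        combined, node_ids=ca_rids, frame_masks=combined_masks)
    state["pca_model"] = model
    report.summary["pc1_variance_fraction"] = float(model.variance_fractions[0])
    report.summary["pc2_variance_fraction"] = float(model.variance_fractions[1])

    per_cond_models = {}
    proj_by_cond = {}
    offset = 0
    for n in names:
        m, p = dynamics.cartesian_pca(coords_by_cond[n],
                                      frame_masks=bound_masks[n])
        per_cond_models[n] = m
        nf = sum(int(np.sum(mm)) for mm in bound_masks[n])
        proj_by_cond[n] = projections[offset:offset + nf, :2]
        offset += nf
    if len(names) >= 2:
        report.summary["rmsip_conditions"] = dynamics.rmsip(
            per_cond_models[names[0]], per_cond_models[names[1]], k=10)
        density = dynamics.projection_density(proj_by_cond)
        state["projection_density"] = density
        for n in names:
            report.summary[f"pc_tail_fraction_{n}"] = (
                density.summaries[n]["tail_fraction"])
    if write_outputs:
        proj_df = pd.DataFrame({
            "condition": np.concatenate(
                [[n] * len(proj_by_cond[n]) for n in names]),
            "pc1": np.concatenate([proj_by_cond[n][:, 0] for n in names]),
            "pc2": np.concatenate([proj_by_cond[n][:, 1] for n in names]),
        })
        _write_tsv(proj_df, out / "pca_projections.tsv")
    report.stages["pca"] = "ok"

    # --- network ------------------------------------------------------
    report.stages["_current"] = "network"
    node_rows = top.indices_of(
        SelectionExpr(atom_names=("CA",)).resolve(top))
    node_rids = [top.atom(a).residue_id
                 for a in SelectionExpr(atom_names=("CA",)).resolve(top)]
    net_results = {}
    for n in names:
        coords = [t.coords[:, node_rows] for t in aligned[n]]
        corr = dynamics.cross_correlation(coords, node_rids,
                                          frame_masks=bound_masks[n])
        net = network.build_network(corr, config.network_threshold)
        parts = network.detect_communities(net)
        paths = network.suboptimal_paths(net, config.path_sources,
                                         config.path_sinks, config.k_paths)
        frac = (network.fraction_through(paths, config.pin_residues)
                if len(paths) else float("nan"))
        net_results[n] = {"corr": corr, "network": net, "partition": parts,
                          "paths": paths, "pin_fraction": frac}
        report.summary[f"n_paths_{n}"] = len(paths)
        report.summary[f"pin_path_fraction_{n}"] = frac
        report.summary[f"n_communities_{n}"] = len(parts.sizes)
        if write_outputs:
            edges = pd.DataFrame(
                [{"a": a, "b": b, "corr": d["corr"], "weight": d["weight"]}
                 for a, b, d in net.graph.edges(data=True)]
            )
            _write_tsv(edges, out / f"network_edges_{n}.tsv")
    state["network"] = net_results
    report.stages["network"] = "ok"

    # --- manifest -----------------------------------------------------
    if write_outputs:
        for f in sorted(out.glob("*.tsv")):
            report.manifest[f.name] = _sha256(f)
    report.stages["report"] = "ok"
    return state
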