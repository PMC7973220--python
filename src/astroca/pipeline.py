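"""End-to-end experiment orchestration.

Two reference experiments mirror the package's validation workflow:

* ``reproduce_single_cell``: simulate synthetic single-astrocyte templates
  at low (0.005 Hz) and high (0.01 Hz) synaptic drive on identical
  template/solver seeds, then summarise event counts (large/small), event
  areas/durations with CCDF power-law slopes, and baseline Ca2+/IP3
  profiles binned by AVF.
* ``reproduce_network``: tile several cells into a network template, run
  it, and derive cellwise traces, the activity-fraction map, the
  repeatability map and the three template perturbations (unlink,
  flatten-AVF, ablate), all sharing the unperturbed spike trains.

Scale presets: "desk" runs in minutes on one CPU with miniature cells and
shortened protocols; "full" matches the reference operating point
(0.275 um grid step, 2000 s burn-in, 2500 s recording, 27 templates) and
is intended for long batch runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dynamics import ParameterSet
from .drive import calibrate_pulse, sample_spike_trains
from .events import (
    baseline_map,
    ccdf,
    classify_events,
    detect_events,
    fit_slope,
    initiation_map,
)
from .morphology import (
    build_library,
    encode_template,
    generate_synthetic_astrocyte,
    intensity_to_avf,
)
from .patterns import (
    ablate_region,
    activity_fraction_map,
    cellwise_traces,
    flatten_avf,
    repeatability_score,
)
from .solver import Protocol, integrate, run_experiment
from .solver import compile as compile_template
from .tiling import (
    build_draft,
    make_seed_lattice,
    relax_boundaries,
    assemble_network,
    voronoi_patches,
)

__all__ = ["ExperimentConfig", "desk_config", "full_config",
           "make_templates", "reproduce_single_cell", "reproduce_network"]


@dataclass
class ExperimentConfig:
    """Everything needed to re-run an experiment deterministically."""

    scale: str = "desk"
    # template generation
    n_templates: int = 3
    template_seed: int = 100
    extent: float = 28.0
    pixel_size: float = 0.55
    soma_radius: float = 3.5
    n_primary_branches: int = 5
    # protocol
    burn_in: float = 200.0
    record: float = 500.0
    p_syn_levels: tuple = (0.005, 0.01)
    drive_seed: int = 1
    save_stride: float = 0.5
    # network tiling
    n_cells_x: int = 2
    n_cells_y: int = 2
    cell_spacing: float = 24.0
    jitter_sigma: float = 4.0
    n_augment: int = 8
    # model parameters (overrides applied on top of the defaults)
    param_overrides: dict = field(default_factory=dict)

    def params(self) -> ParameterSet:
        return ParameterSet(**{"dx": self.pixel_size, **self.param_overrides})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        d["p_syn_levels"] = tuple(d["p_syn_levels"])
        return cls(**d)


def desk_config(**overrides) -> ExperimentConfig:
    """Miniature single-CPU preset (minutes, not days)."""
    return replace(ExperimentConfig(), **overrides)


def full_config(**overrides) -> ExperimentConfig:
    """Reference-scale preset: 0.275 um step, 2000 s + 2500 s, 27 templates,
    ~50 um lattice spacing with sigma = 10 um jitter for ~40-cell networks."""
    cfg = ExperimentConfig(
        scale="full", n_templates=27, extent=60.0, pixel_size=0.275,
        soma_radius=5.0, n_primary_branches=6, burn_in=2000.0, record=2500.0,
        n_cells_x=7, n_cells_y=6, cell_spacing=50.0, jitter_sigma=10.0,
        n_augment=250,
    )
    return replace(cfg, **overrides)


def make_templates(config: ExperimentConfig):
    """Deterministic synthetic single-cell templates for this config."""
    templates = []
    for i in range(config.n_templates):
        img = generate_synthetic_astrocyte(
            extent=config.extent, pixel_size=config.pixel_size,
            soma_radius=config.soma_radius,
            n_primary_branches=config.n_primary_branches,
            seed=config.template_seed + i,
        )
        templates.append(encode_template(intensity_to_avf(img)))
    return templates


def _calibrated_params(config: ExperimentConfig) -> ParameterSet:
    p = config.params()
    d_rel = calibrate_pulse(p, target_peak=1.2, dx=config.pixel_size)
    return p.replace(d_rel=d_rel)


def _binned_baseline(recording, n_bins: int = 5):
    """Mean baseline Ca2+ and IP3 per AVF bin (bin edges over [r_min, 1])."""
    grid = recording.grid
    base_ca = baseline_map(recording)
    base_ip3 = np.percentile(recording.fields["ip3"], 20, axis=0)
    edges = np.linspace(grid.r.min(), grid.r.max() + 1e-9, n_bins + 1)
    idx = np.digitize(grid.r, edges) - 1
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() < 3:
            continue
        rows.append(dict(
            r_lo=float(edges[b]), r_hi=float(edges[b + 1]),
            n_pixels=int(sel.sum()),
            ca_baseline=float(base_ca[sel].mean()),
            ip3_baseline=float(base_ip3[sel].mean()),
        ))
    return rows


def reproduce_single_cell(config: ExperimentConfig, outdir=None,
                          keep_recordings: bool = False) -> dict:
    """Run the single-cell drive-level comparison and summarise it.

    Both drive levels run on the same templates with the same solver and
    drive seeds (only the Poisson rate differs).  Returns a report dict;
    with ``outdir`` also writes events CSV, CCDF CSVs and a markdown
    summary.
    """
    params = _calibrated_params(config)
    templates = make_templates(config)
    report = {
        "config": json.loads(config.to_json()),
        "d_rel": params.d_rel,
        "per_template": [],
        "pooled": {},
    }
    pooled = {p: {"areas": [], "durations": []} for p in config.p_syn_levels}
    recordings = {}
    for ti, tpl in enumerate(templates):
        cell_area = float(tpl.mask.sum()) * config.pixel_size**2
        entry = {"template": ti, "cell_area_um2": cell_area, "levels": {}}
        for p_syn in config.p_syn_levels:
            proto = Protocol(burn_in=config.burn_in, record=config.record,
                             p_syn=p_syn, drive_seed=config.drive_seed + ti,
                             save_stride=config.save_stride)
            rec = run_experiment(tpl, params, proto)
            catalog = detect_events(rec)
            large, small = classify_events(catalog, cell_area)
            pooled[p_syn]["areas"].append(catalog.areas)
            pooled[p_syn]["durations"].append(catalog.durations)
            entry["levels"][str(p_syn)] = {
                "n_events": len(catalog),
                "n_large": len(large),
                "n_small": len(small),
                "mean_area_large": float(np.mean([e.area_um2 for e in large]))
                if large else None,
                "mean_area_small": float(np.mean([e.area_um2 for e in small]))
                if small else None,
                "baseline_by_avf": _binned_baseline(rec),
                "n_clamped": rec.n_clamped,
            }
            if keep_recordings:
                recordings[(ti, p_syn)] = rec
            if outdir is not None:
                out = Path(outdir)
                out.mkdir(parents=True, exist_ok=True)
                catalog.to_dataframe().to_csv(
                    out / f"events_t{ti}_p{p_syn}.csv", index=False)
                if len(catalog):
                    sites = initiation_map(catalog)
                    np.savetxt(out / f"init_sites_t{ti}_p{p_syn}.csv",
                               np.vstack([s["init_pixels"] for s in sites]),
                               fmt="%d", delimiter=",",
                               header="y,x", comments="")
        report["per_template"].append(entry)

    for p_syn in config.p_syn_levels:
        areas = np.concatenate(pooled[p_syn]["areas"]) \
            if pooled[p_syn]["areas"] else np.empty(0)
        durs = np.concatenate(pooled[p_syn]["durations"]) \
            if pooled[p_syn]["durations"] else np.empty(0)
        entry = {"n_events": int(areas.size)}
        if areas.size >= 10:
            curve_a = ccdf(areas)
            entry["area_slope"] = fit_slope(curve_a)
            entry["area_fit_window"] = list(curve_a.fit_window)
            curve_d = ccdf(durs)
            entry["duration_slope"] = fit_slope(curve_d)
            entry["duration_fit_window"] = list(curve_d.fit_window)
            if outdir is not None:
                np.savetxt(Path(outdir) / f"ccdf_areas_p{p_syn}.csv",
                           np.column_stack([curve_a.x, curve_a.survival]),
                           delimiter=",", header="area_um2,survival",
                           comments="")
                np.savetxt(Path(outdir) / f"ccdf_durations_p{p_syn}.csv",
                           np.column_stack([curve_d.x, curve_d.survival]),
                           delimiter=",", header="duration_s,survival",
                           comments="")
        report["pooled"][str(p_syn)] = entry

    if outdir is not None:
        _write_single_cell_markdown(report, Path(outdir) / "report.md")
        (Path(outdir) / "config.json").write_text(config.to_json())
    if keep_recordings:
        report["_recordings"] = recordings
    return report


def _write_single_cell_markdown(report: dict, path: Path) -> None:
    lines = ["# Single-cell drive comparison", ""]
    for entry in report["per_template"]:
        lines.append(f"## Template {entry['template']} "
                     f"(area {entry['cell_area_um2']:.0f} um^2)")
        for level, st in entry["levels"].items():
            lines.append(
                f"- p_syn = {level} Hz: {st['n_events']} events "
                f"({st['n_large']} large / {st['n_small']} small)")
        lines.append("")
    lines.append("## Pooled CCDF slopes")
    for level, st in report["pooled"].items():
        if "area_slope" in st:
            lines.append(f"- p_syn = {level} Hz: area slope "
                         f"{st['area_slope']:.2f}, duration slope "
                         f"{st['duration_slope']:.2f} "
                         f"({st['n_events']} events)")
    path.write_text("\n".join(lines) + "\n")


def build_network_template(config: ExperimentConfig, seed: int | None = None):
    """Library -> jittered lattice -> Voronoi -> match -> relax -> template."""
    seed = config.template_seed if seed is None else seed
    progenitors = [
        generate_synthetic_astrocyte(
            extent=config.cell_spacing * 1.15, pixel_size=config.pixel_size,
            soma_radius=config.soma_radius,
            n_primary_branches=config.n_primary_branches, seed=seed + i)
        for i in range(max(2, config.n_templates))
    ]
    library = build_library(progenitors, n_augment=config.n_augment,
                            seed=seed + 1000)
    extent = (config.n_cells_x * config.cell_spacing,
              config.n_cells_y * config.cell_spacing)
    lattice = make_seed_lattice(extent, spacing=config.cell_spacing,
                                jitter_sigma=config.jitter_sigma,
                                seed=seed + 2000)
    patches = voronoi_patches(lattice)
    draft = build_draft(patches, library)
    relaxed = relax_boundaries(draft, n_iter=25, step=0.5)
    return assemble_network(relaxed, library, pixel_size=config.pixel_size,
                            max_overlap=1.0)


def reproduce_network(config: ExperimentConfig, outdir=None,
                      p_syn: float | None = None,
                      perturbations: bool = True,
                      spike_level: float = 0.2,
                      repeat_kwargs: dict | None = None) -> dict:
    """Build a multicellular template, run it, and analyse collective
    dynamics including the three template perturbations.

    All perturbation runs reuse the unperturbed run's spike trains where
    the astrocyte mask is unchanged (unlink, flatten) so differences are
    attributable to the template alone.
    """
    params = _calibrated_params(config)
    p_syn = config.p_syn_levels[-1] if p_syn is None else p_syn
    template = build_network_template(config)
    proto = Protocol(burn_in=config.burn_in, record=config.record,
                     p_syn=p_syn, drive_seed=config.drive_seed,
                     save_stride=config.save_stride)
    rec = run_experiment(template, params, proto)
    traces = cellwise_traces(rec, spike_threshold=spike_level)
    activity = activity_fraction_map(rec)
    rep_kw = dict(patch=5.0, stride=2.5, min_spikes=10, spike_level=0.5,
                  window=50.0, point_level=0.2)
    rep_kw.update(repeat_kwargs or {})
    repeat = repeatability_score(rec, **rep_kw)
    report = {
        "config": json.loads(config.to_json()),
        "p_syn": p_syn,
        "n_cells": template.n_cells,
        "n_events": None,
        "spikes_per_cell": {t.cell_id: int(t.spike_times.size)
                            for t in traces},
        "activity_fraction_mean": float(np.nanmean(activity)),
        "repeatability": repeat,
        "recording": rec,
        "template": template,
        "traces": traces,
    }
    catalog = detect_events(rec)
    report["n_events"] = len(catalog)
    labels_per_event = []
    lab = rec.grid.domain_labels
    for e in catalog.events:
        sub = lab[e.bbox]
        labels_per_event.append(
            len(np.unique(sub[e.footprint & (sub > 0)])))
    report["n_multicellular_events"] = int(
        sum(1 for n in labels_per_event if n >= 2))

    if perturbations:
        trains = sample_spike_trains(
            rec.grid.n_mask, config.burn_in + config.record, p_syn,
            seed=config.drive_seed)
        # unlink the most repeatable cell
        scores = {}
        for t in traces:
            sel = rec.grid.domain_labels == t.cell_id
            vals = repeat.score[sel]
            scores[t.cell_id] = np.nanmean(vals) if np.isfinite(vals).any() \
                else -np.inf
        hub = max(scores, key=scores.get)
        rec_unlink = run_experiment(template, params, proto,
                                    severed_cells={hub}, trains=trains)
        # flatten / ablate the initiation sites of the largest events
        region = np.zeros(template.shape, dtype=bool)
        if len(catalog):
            for s in initiation_map(catalog, top_n=10):
                for y, x in s["init_pixels"]:
                    region[max(0, y - 2):y + 3, max(0, x - 2):x + 3] = True
        region &= template.mask
        pert = {"unlinked_cell": hub,
                "unlink": repeatability_score(rec_unlink, **rep_kw)}
        if region.any():
            tpl_flat = flatten_avf(template, region)
            rec_flat = run_experiment(tpl_flat, params, proto, trains=trains)
            pert["flatten"] = repeatability_score(rec_flat, **rep_kw)
            tpl_abl = ablate_region(template, region)
            rec_abl = run_experiment(tpl_abl, params, proto)
            pert["ablate"] = repeatability_score(rec_abl, **rep_kw)
            pert["region_px"] = int(region.sum())
        report["perturbations"] = pert

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rec.save(out / "network_run.h5")
        np.savetxt(out / "activity_fraction.csv", activity, delimiter=",")
        with open(out / "cell_spikes.csv", "w") as fh:
            fh.write("cell_id,n_spikes\n")
            for t in traces:
                fh.write(f"{t.cell_id},{t.spike_times.size}\n")
        (out / "config.json").write_text(config.to_json())
    return report
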