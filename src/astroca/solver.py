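"""Compile raster templates to grids and integrate the full model.

The compiled grid keeps cytosolic fields (Ca2+, ER Ca2+, IP3, IP3R gate) on
a compact index over astrocyte-mask pixels and extracellular glutamate on
the full raster.  Diffusion follows an AVF-scaled pairwise-flux scheme: for
an edge (i, j) the flux is ``F = D * rt^2 / dx^2 * (c_i - c_j)`` with
``rt = sqrt(r_i r_j)``; pixel i receives ``-F * rt/r_i`` and pixel j
``+F * rt/r_j``.  This reduces to the standard r^2-scaled 5-point Laplacian
for uniform AVF, implements the volume-ratio scaling of exchange between
pixels of unequal AVF, and conserves AVF-weighted mass ``sum(r c)`` exactly.
Gap-junction coupling between neighbouring cells is simply the same
diffusive exchange across domain borders; "unlinking" a cell severs those
edges for Ca2+/IP3 while extracellular glutamate continues to diffuse.

Integration is fixed-step classic RK4 (dt = 0.002 s by default).  The only
stochastic input, the piecewise-constant quantal glutamate pulse train, is
evaluated at the RK4 stage times, which is exact for piecewise-constant
forcing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .dynamics import ModelState, ParameterSet
from .drive import SpikeTrainSet, sample_spike_trains
from .morphology import SpatialTemplate, avf_to_svr, decode_template

__all__ = ["CompiledGrid", "Recording", "compile", "diffusion_rates",
           "stability_report", "integrate", "run_experiment", "Protocol"]


@dataclass
class CompiledGrid:
    """Per-pixel geometry and adjacency compiled from a SpatialTemplate."""

    shape: tuple[int, int]
    mask_idx: np.ndarray        # flat grid indices of astrocyte pixels
    r: np.ndarray               # AVF per mask pixel
    s: np.ndarray               # SVR weight per mask pixel
    domain_labels: np.ndarray   # (H, W) int labels, 0 = extracellular
    dx: float                   # grid step, um
    edges: tuple[np.ndarray, np.ndarray]       # mask-compact (i, j) pairs, Ca/IP3
    grid_edges: tuple[np.ndarray, np.ndarray]  # flat grid (i, j) pairs, Glu
    severed_cells: frozenset = frozenset()

    @property
    def n_mask(self) -> int:
        return self.mask_idx.size

    @property
    def n_grid(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m.reshape(-1)[self.mask_idx] = True
        return m

    @property
    def cell_labels(self) -> np.ndarray:
        """Domain label per mask pixel (compact order)."""
        return self.domain_labels.reshape(-1)[self.mask_idx]

    def edge_weights(self, D: float):
        """(w, gi, gj) arrays for the pairwise AVF-scaled flux at diffusivity D."""
        i, j = self.edges
        rt = np.sqrt(self.r[i] * self.r[j])
        w = D * rt**2 / self.dx**2
        return w, rt / self.r[i], rt / self.r[j]


def _grid_edges(shape, mask_flat=None):
    """4-connectivity edge list over a raster (optionally restricted)."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    vi = idx[:-1, :].ravel(); vj = idx[1:, :].ravel()
    hi = idx[:, :-1].ravel(); hj = idx[:, 1:].ravel()
    ei = np.concatenate([vi, hi]); ej = np.concatenate([vj, hj])
    if mask_flat is not None:
        keep = mask_flat[ei] & mask_flat[ej]
        ei, ej = ei[keep], ej[keep]
    return ei, ej


def compile(template: SpatialTemplate, params: ParameterSet,
            severed_cells=frozenset()) -> CompiledGrid:
    """Compile a template: decode AVF, compute SVR, build adjacency.

    ``severed_cells``: cells whose inter-domain Ca2+/IP3 edges are removed
    ("unlinked" from the gap-junction network); glutamate adjacency is
    unaffected.
    """
    avf, labels = decode_template(template, r_min=params.r_min)
    r_map = avf.r
    mask = r_map > 0
    if np.any(mask & (r_map < params.r_min - 1e-12)):
        raise ValueError("astrocyte pixels with AVF below r_min")
    mask_flat = mask.reshape(-1)
    mask_idx = np.nonzero(mask_flat)[0]
    grid_to_mask = np.full(mask_flat.size, -1, dtype=np.int64)
    grid_to_mask[mask_idx] = np.arange(mask_idx.size)

    ei, ej = _grid_edges(template.shape, mask_flat)
    mi, mj = grid_to_mask[ei], grid_to_mask[ej]
    severed_cells = frozenset(int(c) for c in severed_cells)
    if severed_cells:
        lab = labels.reshape(-1)
        li, lj = lab[ei], lab[ej]
        cut = (li != lj) & (
            np.isin(li, list(severed_cells)) | np.isin(lj, list(severed_cells)))
        mi, mj = mi[~cut], mj[~cut]
    gi, gj = _grid_edges(template.shape)
    dx = template.pixel_size
    r = r_map.reshape(-1)[mask_idx]
    return CompiledGrid(
        shape=template.shape, mask_idx=mask_idx, r=r,
        s=avf_to_svr(r, slope=params.svr_slope),
        domain_labels=labels, dx=dx,
        edges=(mi, mj), grid_edges=(gi, gj),
        severed_cells=severed_cells,
    )


def diffusion_rates(field: np.ndarray, species: str, grid: CompiledGrid,
                    params: ParameterSet) -> np.ndarray:
    """Diffusive rate of change (uM/s) for one species; reference NumPy path.

    Ca2+/IP3 fields are defined on the astrocyte mask (compact, length
    n_mask); glutamate on the full flattened grid.  No-flux boundary
    conditions hold at the template edge and, for cytosolic species, at the
    astrocyte/extracellular interface.
    """
    field = np.asarray(field, dtype=float)
    if species in ("Ca", "IP3"):
        if field.shape != (grid.n_mask,):
            raise ValueError("cytosolic fields live on the astrocyte mask")
        D = params.D_ca if species == "Ca" else params.D_ip3
        i, j = grid.edges
        w, fac_i, fac_j = grid.edge_weights(D)
        f = w * (field[i] - field[j])
        out = np.zeros_like(field)
        np.subtract.at(out, i, f * fac_i)
        np.add.at(out, j, f * fac_j)
        return out
    if species == "Glu":
        if field.shape != (grid.n_grid,):
            raise ValueError("glutamate lives on the full grid")
        i, j = grid.grid_edges
        w = params.D_glu / grid.dx**2
        f = w * (field[i] - field[j])
        out = np.zeros_like(field)
        np.subtract.at(out, i, f)
        np.add.at(out, j, f)
        return out
    raise ValueError(f"unknown species {species!r}")


def stability_report(grid: CompiledGrid, params: ParameterSet) -> dict:
    """Explicit-scheme diffusive stability diagnostics for this grid.

    Reports the naive forward-Euler bound dt < dx^2/(4 D max r^2) and the
    classic-RK4 real-axis bound dt < 2.785/lambda_max with
    lambda_max = 8 D max(r^2)/dx^2 (5-point Laplacian worst case).
    """
    d_max = max(params.D_ca, params.D_ip3)
    r2 = float(np.max(grid.r) ** 2) if grid.n_mask else 0.0
    euler = grid.dx**2 / (4.0 * d_max * r2) if r2 else np.inf
    lam = 8.0 * d_max * r2 / grid.dx**2 if r2 else 0.0
    rk4 = 2.785 / lam if lam else np.inf
    return {
        "dt": params.dt,
        "euler_bound": euler,
        "rk4_bound": rk4,
        "dt_ok_euler": params.dt < euler,
        "dt_ok_rk4": params.dt < rk4,
    }


@dataclass
class Recording:
    """TXY trajectory of selected fields at the save stride.

    ``fields`` maps names to float32 arrays: cytosolic fields are
    (n_frames, n_mask), glutamate (if recorded) is (n_frames, n_grid).
    Metadata (config JSON, seeds, template raster, burn-in state) is
    sufficient to re-run the simulation bit-identically.
    """

    times: np.ndarray
    fields: dict
    grid: CompiledGrid
    params: ParameterSet
    seeds: dict = field(default_factory=dict)
    burn_in: float = 0.0
    burn_state: np.ndarray | None = None   # (4, n_mask): ca, er, ip3, q
    final_state: ModelState | None = None
    n_clamped: int = 0
    template_rgb: np.ndarray | None = None

    @property
    def frame_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def dense(self, name: str) -> np.ndarray:
        """Field as a dense (T, H, W) array (zeros outside support)."""
        arr = self.fields[name]
        if name == "glu":
            return arr.reshape(-1, *self.grid.shape)
        out = np.zeros((arr.shape[0], self.grid.n_grid), dtype=arr.dtype)
        out[:, self.grid.mask_idx] = arr
        return out.reshape(-1, *self.grid.shape)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["config"] = self.params.to_json()
            h5.attrs["seeds"] = json.dumps(self.seeds)
            h5.attrs["burn_in"] = self.burn_in
            h5.attrs["n_clamped"] = self.n_clamped
            h5.attrs["dx"] = self.grid.dx
            h5.create_dataset("times", data=self.times)
            for k, v in self.fields.items():
                h5.create_dataset(f"fields/{k}", data=v, compression="gzip")
            h5.create_dataset("grid/mask_idx", data=self.grid.mask_idx)
            h5.create_dataset("grid/r", data=self.grid.r)
            h5.create_dataset("grid/domain_labels", data=self.grid.domain_labels)
            h5.attrs["shape"] = self.grid.shape
            if self.burn_state is not None:
                h5.create_dataset("burn_state", data=self.burn_state)
            if self.template_rgb is not None:
                h5.create_dataset("template_rgb", data=self.template_rgb)

    @classmethod
    def load(cls, path) -> "Recording":
        import h5py

        from .morphology import avf_to_svr

        with h5py.File(path, "r") as h5:
            params = ParameterSet.from_dict(json.loads(h5.attrs["config"]))
            shape = tuple(int(x) for x in h5.attrs["shape"])
            mask_idx = h5["grid/mask_idx"][...]
            r = h5["grid/r"][...]
            labels = h5["grid/domain_labels"][...]
            mask_flat = np.zeros(shape[0] * shape[1], dtype=bool)
            mask_flat[mask_idx] = True
            ei, ej = _grid_edges(shape, mask_flat)
            g2m = np.full(mask_flat.size, -1, dtype=np.int64)
            g2m[mask_idx] = np.arange(mask_idx.size)
            grid = CompiledGrid(
                shape=shape, mask_idx=mask_idx, r=r,
                s=avf_to_svr(r, slope=params.svr_slope),
                domain_labels=labels, dx=float(h5.attrs["dx"]),
                edges=(g2m[ei], g2m[ej]), grid_edges=_grid_edges(shape),
            )
            rec = cls(
                times=h5["times"][...],
                fields={k: h5[f"fields/{k}"][...] for k in h5["fields"]},
                grid=grid, params=params,
                seeds=json.loads(h5.attrs["seeds"]),
                burn_in=float(h5.attrs["burn_in"]),
                n_clamped=int(h5.attrs["n_clamped"]),
            )
            if "burn_state" in h5:
                rec.burn_state = h5["burn_state"][...]
            if "template_rgb" in h5:
                rec.template_rgb = h5["template_rgb"][...]
        return rec


def _initial_state(grid: CompiledGrid, params: ParameterSet) -> ModelState:
    """Per-pixel zero-drive rest state (computed once per unique AVF value)."""
    from .dynamics import resting_state

    uniq, inv = np.unique(grid.r, return_inverse=True)
    rest = resting_state(params, uniq)
    glu = np.full(grid.n_grid, float(params.glu_amb))
    return ModelState(
        ca_c=np.asarray(rest.ca_c)[inv], ca_er=np.asarray(rest.ca_er)[inv],
        ip3=np.asarray(rest.ip3)[inv], glu=glu, q=np.asarray(rest.q)[inv],
    )


def integrate(grid: CompiledGrid, params: ParameterSet, T: float,
              trains: SpikeTrainSet | None = None,
              init: ModelState | None = None,
              burn_in: float = 0.0,
              save_stride: float | None = None,
              record_glu: bool = False,
              seeds: dict | None = None) -> Recording:
    """Integrate the full model for ``burn_in + T`` seconds of model time.

    Frames are recorded every ``save_stride`` seconds starting at the end of
    the burn-in.  ``trains`` carries quantal-release times on the astrocyte
    mask pixels over the whole span (burn-in included); ``init`` defaults to
    the per-pixel zero-drive rest state.
    """
    dt = params.dt
    if save_stride is None:
        save_stride = params.save_stride
    save_every = max(1, int(round(save_stride / dt)))
    skip = int(round(burn_in / dt))
    n_rec = int(round(T / dt))
    n_rec = (n_rec // save_every) * save_every
    n_total = skip + n_rec

    rep = stability_report(grid, params)
    if not rep["dt_ok_euler"]:
        msg = (f"dt={dt} exceeds the forward-Euler diffusive bound "
               f"{rep['euler_bound']:.4g}s")
        if rep["dt_ok_rk4"]:
            msg += f" but satisfies the RK4 bound {rep['rk4_bound']:.4g}s"
            warnings.warn(msg)
        else:
            warnings.warn(msg + f" and the RK4 bound {rep['rk4_bound']:.4g}s; "
                          "expect instability")

    if init is None:
        init = _initial_state(grid, params)
    ca, er, ip3, glu, q = (np.array(a, dtype=float) for a in
                           (init.ca_c, init.ca_er, init.ip3, init.glu, init.q))
    # re-order glu if given on the grid shape
    if glu.ndim == 2:
        glu = glu.reshape(-1)
    if ca.shape != (grid.n_mask,) or glu.shape != (grid.n_grid,):
        raise ValueError("init state has wrong support")

    if trains is None:
        ev_t = np.empty(0)
        ev_g = np.empty(0, dtype=np.int64)
    else:
        if trains.n_pixels != grid.n_mask:
            raise ValueError("spike trains must cover the astrocyte mask pixels")
        px, ev_t = trains.flatten()
        ev_g = grid.mask_idx[px]
    amp = params.A  # release-rate step per active pulse, uM/s

    kin = _kernel.pack_kinetics(params)
    mi, mj = grid.edges
    w_ca, fac_i, fac_j = grid.edge_weights(params.D_ca)
    w_ip3 = grid.edge_weights(params.D_ip3)[0]
    gi, gj = grid.grid_edges
    w_glu = params.D_glu / grid.dx**2

    n_frames = n_rec // save_every + 1
    rec_ca = np.empty((n_frames, grid.n_mask), dtype=np.float32)
    rec_ip3 = np.empty((n_frames, grid.n_mask), dtype=np.float32)
    rec_glu = np.empty((n_frames if record_glu else 0,
                        grid.n_grid if record_glu else 0), dtype=np.float32)
    burn_out = np.empty((4, grid.n_mask))
    g2m = np.full(grid.n_grid, -1, dtype=np.int64)
    g2m[grid.mask_idx] = np.arange(grid.n_mask)

    status, bad_step, n_clamped = _kernel.rk4_run(
        ca, er, ip3, q, glu,
        grid.s, 1.0 - grid.s, (1.0 - grid.s) / params.c1, grid.mask_idx, kin,
        mi.astype(np.int64), mj.astype(np.int64), w_ca, w_ip3, fac_i, fac_j,
        gi.astype(np.int64), gj.astype(np.int64), w_glu,
        np.asarray(ev_t, dtype=float), np.asarray(ev_g, dtype=np.int64),
        amp, params.d_rel, dt, n_total, skip, save_every,
        rec_ca, rec_ip3, rec_glu, record_glu, burn_out,
    )
    if status != 0:
        bad = np.flatnonzero(~np.isfinite(ca))
        where = grid.mask_idx[bad[0]] if bad.size else -1
        raise FloatingPointError(
            f"non-finite state at step {bad_step} (t={bad_step * dt:.3f}s), "
            f"grid pixel {where}")

    times = burn_in + save_stride * np.arange(n_frames)
    fields = {"ca_c": rec_ca, "ip3": rec_ip3}
    if record_glu:
        fields["glu"] = rec_glu
    return Recording(
        times=times, fields=fields, grid=grid, params=params,
        seeds=seeds or {}, burn_in=burn_in, burn_state=burn_out,
        final_state=ModelState(ca_c=ca, ca_er=er, ip3=ip3, glu=glu, q=q),
        n_clamped=int(n_clamped),
    )


@dataclass
class Protocol:
    """Drive/recording protocol of a simulation experiment."""

    burn_in: float = 2000.0
    record: float = 2500.0
    p_syn: float = 0.005
    drive_seed: int = 0
    save_stride: float = 0.5
    record_glu: bool = False


def run_experiment(template: SpatialTemplate, params: ParameterSet,
                   protocol: Protocol,
                   severed_cells=frozenset(),
                   trains: SpikeTrainSet | None = None) -> Recording:
    """Compile, burn in and record one stochastic-drive experiment.

    The grid step is taken from the template's pixel size.  The spike
    trains span burn-in plus recording; pass ``trains`` explicitly to reuse
    the drive of another run (controlled comparisons across template
    perturbations share the unperturbed drive).
    """
    params = params.replace(dx=template.pixel_size, p_syn=protocol.p_syn)
    grid = compile(template, params, severed_cells=severed_cells)
    total = protocol.burn_in + protocol.record
    if trains is None:
        trains = sample_spike_trains(grid.n_mask, total, protocol.p_syn,
                                     seed=protocol.drive_seed)
    rec = integrate(
        grid, params, T=protocol.record, trains=trains,
        burn_in=protocol.burn_in, save_stride=protocol.save_stride,
        record_glu=protocol.record_glu,
        seeds={"drive_seed": protocol.drive_seed},
    )
    rec.template_rgb = template.rgb
    return rec
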