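"""Stochastic synaptic glutamate drive.

Each astrocyte-occupied pixel is associated with one or a few synapses
whose presynaptic firing is a homogeneous Poisson process of rate ``p_syn``
(Hz).  Every spike triggers quantal glutamate release, modelled as an
instantaneous rise of the release rate to ``A`` (uM/s) for a short duration
``d_rel``: ``xi(t) = A * #{k : t_k <= t < t_k + d_rel}``.  ``d_rel`` is
calibrated (:func:`calibrate_pulse`) so a single event in an isolated pixel
peaks at the reference quantal transient amplitude of 1.2 uM, giving
``d_rel ~ 59 ms`` at the default parameters -- a transient that rises and
decays within ~200 ms.  Total release per event is ``A * d_rel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrainSet", "sample_spike_trains", "release_rate",
           "calibrate_pulse", "peak_closed_form"]


@dataclass
class SpikeTrainSet:
    """Per-pixel Poisson event times on [0, T]."""

    times: list[np.ndarray]  # one strictly-increasing array per pixel, s
    rate: float              # p_syn, Hz
    duration: float          # T, s
    seed: int | None = None

    def __post_init__(self) -> None:
        for t in self.times:
            t = np.asarray(t)
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0
                           or t[-1] > self.duration):
                raise ValueError("event times must be strictly increasing in [0, T]")

    @property
    def n_pixels(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(sum(t.size for t in self.times))

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """(pixel_index, time) arrays sorted by time."""
        if self.n_events == 0:
            return np.empty(0, dtype=np.int64), np.empty(0)
        px = np.concatenate([np.full(t.size, i, dtype=np.int64)
                             for i, t in enumerate(self.times)])
        tt = np.concatenate([np.asarray(t, dtype=float) for t in self.times])
        order = np.argsort(tt, kind="stable")
        return px[order], tt[order]

    def to_csv(self, path) -> None:
        px, tt = self.flatten()
        with open(path, "w") as fh:
            fh.write("pixel_index,time_s\n")
            for i, t in zip(px, tt):
                fh.write(f"{i},{float(t)!r}\n")

    @classmethod
    def from_csv(cls, path, n_pixels: int, rate: float, duration: float
                 ) -> "SpikeTrainSet":
        data = np.genfromtxt(path, delimiter=",", skip_header=1, ndmin=2)
        times = [np.empty(0) for _ in range(n_pixels)]
        if data.size:
            px = data[:, 0].astype(int)
            for i in range(n_pixels):
                times[i] = np.sort(data[px == i, 1])
        return cls(times=times, rate=rate, duration=duration)


def sample_spike_trains(n_pixels: int, T: float, p_syn: float,
                        seed: int = 0) -> SpikeTrainSet:
    """Draw independent homogeneous Poisson spike trains for each pixel.

    Inter-event intervals are i.i.d. Exponential(p_syn); sampling is
    reproducible per (seed, pixel) and independent across pixels (each pixel
    gets its own spawned random stream).
    """
    if p_syn < 0:
        raise ValueError("rate must be non-negative")
    if T <= 0:
        raise ValueError("duration must be positive")
    times: list[np.ndarray] = []
    streams = np.random.SeedSequence(seed).spawn(n_pixels)
    for ss in streams:
        if p_syn == 0:
            times.append(np.empty(0))
            continue
        rng = np.random.default_rng(ss)
        # draw in blocks until past T
        t, out = 0.0, []
        while True:
            gaps = rng.exponential(1.0 / p_syn, size=16)
            for g in gaps:
                t += g
                if t > T:
                    break
                out.append(t)
            if t > T:
                break
        times.append(np.array(out))
    return SpikeTrainSet(times=times, rate=p_syn, duration=T, seed=seed)


def release_rate(t, trains: SpikeTrainSet, pixel: int, A: float,
                 d_rel: float):
    """Exogenous glutamate release rate xi(t) for one pixel, uM/s.

    ``xi(t) = A * #{k : t_k <= t < t_k + d_rel}``; overlapping pulses sum.
    Works on scalar or array ``t``.
    """
    if d_rel <= 0:
        raise ValueError("d_rel must be positive")
    tk = np.asarray(trains.times[pixel], dtype=float)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if tk.size == 0:
        out = np.zeros_like(t_arr)
    else:
        hi = np.searchsorted(tk, t_arr, side="right")
        lo = np.searchsorted(tk, t_arr - d_rel, side="right")
        out = (hi - lo) * A
    return out if np.ndim(t) else float(out[0])


def peak_closed_form(d_rel: float, A: float, tau_glu: float) -> float:
    """Peak glutamate after one isolated pulse, no diffusion.

    For d[Glu]/dt = -Glu/tau + A on [0, d_rel] starting at 0 the peak is
    reached at the pulse end: ``A*tau * (1 - exp(-d_rel/tau))``, saturating
    at ``A*tau`` for long pulses.
    """
    return A * tau_glu * (1.0 - np.exp(-d_rel / tau_glu))


def _simulated_peak(d_rel: float, p, dx: float, n_halo: int = 6) -> float:
    """Peak glutamate of one event at the centre of a small diffusive patch.

    Integrates the (linear) glutamate equation alone with RK4 at the model
    dt on a (2*n_halo+1)^2 all-extracellular patch, release in the centre
    pixel, no-flux boundary.
    """
    n = 2 * n_halo + 1
    glu = np.zeros((n, n))
    k_d = p.D_glu / dx**2
    inv_tau = 1.0 / p.tau_glu
    rate = p.A
    t, dt = 0.0, p.dt
    t_on, t_off = 0.05, 0.05 + d_rel
    peak = 0.0
    n_steps = int(np.ceil((t_off + 6 * p.tau_glu) / dt))

    def rhs(g, tt):
        lap = np.zeros_like(g)
        lap[1:, :] += g[:-1, :] - g[1:, :]
        lap[:-1, :] += g[1:, :] - g[:-1, :]
        lap[:, 1:] += g[:, :-1] - g[:, 1:]
        lap[:, :-1] += g[:, 1:] - g[:, :-1]
        d = (p.glu_amb - g) * inv_tau + k_d * lap
        if t_on <= tt < t_off:
            d[n_halo, n_halo] += rate
        return d

    for _ in range(n_steps):
        k1 = rhs(glu, t)
        k2 = rhs(glu + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = rhs(glu + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = rhs(glu + dt * k3, t + dt - 1e-9)  # (t+dt)^-: see solver kernel
        glu = glu + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        peak = max(peak, glu[n_halo, n_halo])
    return peak


def calibrate_pulse(p, target_peak: float = 1.2, dx: float | None = None,
                    rtol: float = 0.005) -> float:
    """Find d_rel so that a single quantal event peaks at ``target_peak``.

    The closed-form seed from the no-diffusion limit,
    ``d = -tau_Glu * ln(1 - target_peak/(A*tau_Glu))``, is refined by
    bisection against the simulated isolated pixel with glutamate diffusion
    to its neighbours enabled at grid step ``dx`` (default: the parameter
    set's dx).  The peak grows with d_rel and saturates at ``A*tau_Glu``;
    an unreachable target raises with the attainable range.
    """
    if dx is None:
        dx = p.dx
    sat = p.A * p.tau_glu
    if not 0 < target_peak < sat:
        raise ValueError(
            f"target peak outside attainable range (0, {sat:.3g}) uM")
    d_seed = -p.tau_glu * np.log(1.0 - target_peak / sat)
    # bisection against the simulated pixel (peak increases with d_rel);
    # diffusion only drains the pixel, so the no-diffusion seed is a lower
    # bound on the required duration
    lo, hi = d_seed, 8.0 * d_seed + p.tau_glu
    if _simulated_peak(hi, p, dx) < target_peak:
        raise ValueError(
            "target peak unreachable with neighbour diffusion on; "
            f"attainable < {_simulated_peak(hi, p, dx):.3g} uM")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        pk = _simulated_peak(mid, p, dx)
        if abs(pk - target_peak) <= rtol * target_peak:
            return mid
        if pk > target_peak:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
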