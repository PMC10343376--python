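"""Entropy term of the end-point estimate: interaction entropy and normal modes.

The interaction-entropy (IE) method turns the fluctuation of the
receptor–ligand interaction energy into an entropy penalty without any
extra simulation:

    −TΔS = k_B·T · ln ⟨ exp(ΔE_inte / k_B·T) ⟩,   ΔE_inte = E_inte − ⟨E_inte⟩

(k_B·T per mole = R·T).  By Jensen's inequality the estimate is ≥ 0 and
zero only for a constant series; for Gaussian fluctuations of width σ it
converges to σ²/(2RT).  The exponential average is evaluated with
log-sum-exp so large fluctuations cannot overflow, and a diagnostic warns
when σ > 3·RT where the estimator's sampling variance blows up.

Normal-mode (NM) entropy minimizes each species on a caller-supplied
(or toy harmonic) energy surface, builds the mass-weighted Hessian by
central finite differences, and applies the quantum harmonic-oscillator
entropy per retained vibrational mode.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import GAS_CONSTANT, H_OVER_KB, SPEED_OF_LIGHT_CM, rt
from .topology import ComplexTopology, Trajectory

#: conversion of Hessian eigenvalues (kcal/mol/Å²/amu) to ω² (s⁻²):
#: 4184 J/kcal divided by N_A·amu·Å² = 1e-3 kg/mol · 1e-20 m².
_LAMBDA_TO_OMEGA2 = 4184.0 / (1e-3 * 1e-20)


@dataclass
class EntropyEstimate:
    """−TΔS in kcal/mol with its method tag and diagnostics."""

    minus_t_ds: float
    method: str                     # "IE" or "NM"
    temperature: float
    n_samples: int = 0              # IE: series length; NM: frames averaged
    sigma: float = float("nan")     # IE: fluctuation σ of the series
    lowest_frequency: float = float("nan")  # NM: lowest retained ν̃, cm⁻¹


def interaction_entropy(series, temperature: float) -> EntropyEstimate:
    """IE estimate of −TΔS from an interaction-energy series (kcal/mol)."""
    e = np.asarray(series, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("interaction-energy series must be 1-D with n >= 2")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    kt = rt(temperature)
    x = (e - e.mean()) / kt
    value = kt * float(logsumexp(x) - np.log(e.size))
    sigma = float(e.std())
    if sigma > 3.0 * kt:
        warnings.warn(
            f"interaction-energy fluctuation σ={sigma:.2f} kcal/mol exceeds 3·RT"
            f"={3 * kt:.2f}: the IE exponential average converges poorly at this "
            "fluctuation level", RuntimeWarning, stacklevel=2)
    return EntropyEstimate(minus_t_ds=max(value, 0.0), method="IE",
                           temperature=temperature, n_samples=e.size, sigma=sigma)


class HarmonicForceField:
    """Toy bonded surface: harmonic bonds and angles with analytic gradient.

    ``bonds`` are (i, j, k_b kcal/mol/Å², r0 Å); ``angles`` are
    (i, j, k, k_theta kcal/mol/rad², theta0 rad) with j the vertex.
    Indices are 0-based positions into the coordinate array.
    """

    def __init__(self, bonds, angles=()):
        self.bonds = [(int(i), int(j), float(kb), float(r0)) for i, j, kb, r0 in bonds]
        self.angles = [(int(i), int(j), int(k), float(kt), float(t0))
                       for i, j, k, kt, t0 in angles]

    def energy(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        e = 0.0
        for i, j, kb, r0 in self.bonds:
            r = np.linalg.norm(coords[i] - coords[j])
            e += kb * (r - r0) ** 2
        for i, j, k, kt, t0 in self.angles:
            e += kt * (self._angle(coords, i, j, k) - t0) ** 2
        return e

    @staticmethod
    def _angle(coords, i, j, k) -> float:
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        g = np.zeros_like(coords)
        for i, j, kb, r0 in self.bonds:
            d = coords[i] - coords[j]
            r = np.linalg.norm(d)
            f = 2.0 * kb * (r - r0) / r * d
            g[i] += f
            g[j] -= f
        if self.angles:
            # angle term by central differences; adequate at toy scale
            h = 1e-6
            flat = coords.ravel().copy()
            for idx in sorted({n for a in self.angles for n in a[:3]}):
                for d in range(3):
                    p = 3 * idx + d
                    flat[p] += h
                    ep = self._angle_energy(flat.reshape(-1, 3))
                    flat[p] -= 2 * h
                    em = self._angle_energy(flat.reshape(-1, 3))
                    flat[p] += h
                    g[idx, d] += (ep - em) / (2 * h)
        return g.ravel()

    def _angle_energy(self, coords) -> float:
        return sum(kt * (self._angle(coords, i, j, k) - t0) ** 2
                   for i, j, k, kt, t0 in self.angles)


@dataclass
class NormalModeResult:
    """Vibrational analysis of one minimized species."""

    frequencies: np.ndarray = field(repr=False)  # retained ν̃, cm⁻¹, sorted
    n_zero_modes_removed: int = 0
    s_vib: float = 0.0              # kcal/(mol·K)
    minimized_energy: float = 0.0
    gradient_rms: float = 0.0


def qho_entropy(freq_cm: np.ndarray, temperature: float) -> float:
    """Quantum harmonic-oscillator vibrational entropy, kcal/(mol·K)."""
    nu = np.asarray(freq_cm, dtype=float)
    if nu.size == 0:
        return 0.0
    x = H_OVER_KB * SPEED_OF_LIGHT_CM * nu / temperature  # hν/kT
    return float(GAS_CONSTANT * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def normal_mode_entropy(masses, coords, energy_fn, gradient_fn=None,
                        temperature: float = 303.15, linear: bool = False,
                        grad_tol: float = 1e-5, fd_step: float = 1e-4,
                        zero_mode_cm: float = 1.0) -> NormalModeResult:
    """Minimize, diagonalize the mass-weighted Hessian, apply QHO entropy.

    ``energy_fn`` maps a flat (3N,) coordinate vector to kcal/mol.  Six
    near-zero modes are removed for nonlinear species, five for linear
    ones; an imaginary frequency above tolerance raises (not at a
    minimum).  Single atoms have no vibrational modes and return S = 0.
    """
    masses = np.asarray(masses, dtype=float)
    x0 = np.asarray(coords, dtype=float).ravel()
    n = masses.size
    if x0.size != 3 * n:
        raise ValueError("coords/masses size mismatch")
    if n == 1:
        return NormalModeResult(np.array([]), 0, 0.0, float(energy_fn(x0)), 0.0)
    jac = gradient_fn
    res = minimize(energy_fn, x0, jac=jac, method="L-BFGS-B",
                   options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-9})
    x = res.x
    g = gradient_fn(x) if gradient_fn is not None else _fd_gradient(energy_fn, x, fd_step)
    grms = float(np.sqrt(np.mean(np.asarray(g) ** 2)))
    if grms > grad_tol:
        raise RuntimeError(f"minimization did not converge: gradient RMS {grms:.2e} "
                           f"> {grad_tol:.0e} kcal/mol/Å")
    hess = _fd_hessian(energy_fn, x, fd_step)
    invsqrt = 1.0 / np.sqrt(np.repeat(masses, 3))
    mw = hess * np.outer(invsqrt, invsqrt)
    lam = np.linalg.eigvalsh((mw + mw.T) / 2.0)
    omega2 = lam * _LAMBDA_TO_OMEGA2
    nu = np.sign(omega2) * np.sqrt(np.abs(omega2)) / (2.0 * np.pi * SPEED_OF_LIGHT_CM)
    n_trivial = 5 if linear else 6
    if np.any(nu < -zero_mode_cm):
        worst = float(nu.min())
        raise RuntimeError(f"imaginary frequency {abs(worst):.1f}i cm⁻¹ after "
                           "minimization: not at a minimum")
    order = np.argsort(np.abs(nu))
    retained = np.sort(nu[order[n_trivial:]])
    if retained.size and retained.min() <= zero_mode_cm:
        raise RuntimeError("more than the expected number of near-zero modes; "
                           "system may be disconnected or linear")
    return NormalModeResult(frequencies=retained, n_zero_modes_removed=n_trivial,
                            s_vib=qho_entropy(retained, temperature),
                            minimized_energy=float(res.fun), gradient_rms=grms)


def _fd_gradient(fn, x, h):
    g = np.zeros_like(x)
    for p in range(x.size):
        xp = x.copy(); xp[p] += h
        xm = x.copy(); xm[p] -= h
        g[p] = (fn(xp) - fn(xm)) / (2 * h)
    return g


def _fd_hessian(fn, x, h):
    n = x.size
    hess = np.zeros((n, n))
    for p in range(n):
        for q in range(p, n):
            xpp = x.copy(); xpp[p] += h; xpp[q] += h
            xpm = x.copy(); xpm[p] += h; xpm[q] -= h
            xmp = x.copy(); xmp[p] -= h; xmp[q] += h
            xmm = x.copy(); xmm[p] -= h; xmm[q] -= h
            hess[p, q] = hess[q, p] = (fn(xpp) - fn(xpm) - fn(xmp) + fn(xmm)) / (4 * h * h)
    return hess


def nm_binding_entropy(traj: Trajectory, stride: int, temperature: float,
                       energy_fns: dict, gradient_fns: dict | None = None,
                       linear_flags: dict | None = None) -> EntropyEstimate:
    """−TΔS from normal modes of complex, receptor and ligand per frame.

    ``energy_fns`` maps the species names ``complex``/``receptor``/
    ``ligand`` to flat-coordinate energy callables; −TΔS =
    −T·(S_complex − S_receptor − S_ligand) averaged over strided frames.
    """
    from .topology import split_complex

    if stride < 1:
        raise ValueError("stride must be >= 1")
    top = traj.topology
    top.require_complex()
    gradient_fns = gradient_fns or {}
    linear_flags = linear_flags or {}
    masses = np.array([a.mass for a in top.atoms])
    rec_pos = top.segment_positions("receptor")
    lig_pos = top.segment_positions("ligand")
    vals = []
    lowest = np.inf
    for k in range(0, traj.n_frames, stride):
        frame = traj.frames[k]
        ds = 0.0
        for name, m_idx in (("complex", None), ("receptor", rec_pos), ("ligand", lig_pos)):
            m = masses if m_idx is None else masses[m_idx]
            c = frame if m_idx is None else frame[m_idx]
            r = normal_mode_entropy(m, c, energy_fns[name],
                                    gradient_fns.get(name), temperature,
                                    linear=bool(linear_flags.get(name, False)))
            if r.frequencies.size:
                lowest = min(lowest, float(r.frequencies.min()))
            ds += r.s_vib if name == "complex" else -r.s_vib
        vals.append(-temperature * ds)
    return EntropyEstimate(minus_t_ds=float(np.mean(vals)), method="NM",
                           temperature=temperature, n_samples=len(vals),
                           lowest_frequency=float(lowest))
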