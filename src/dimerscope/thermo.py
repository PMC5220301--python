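"""Potential of mean force along the inter-monomer distance and
standard-state binding thermodynamics.

A mean-force profile F(r) sampled along the centre-of-mass separation is
integrated (trapezoid) into a PMF, W(r) = -Int F dr, referenced so that the
mean of W over a flat long-distance window is zero; pointwise errors follow
by quadrature accumulation of segment variances from the mean-force standard
errors. The dissociation constant comes from the 1-D radial configurational
integral over the bound well,

    Ka = C0 * Int_bound 4 pi r^2 exp(-W(r)/RT) dr,   Kd = 1/Ka,

with C0 = 1/1.661 nm^-3 the 1 M standard-state concentration per molecule,
and the binding free energy from the convention

    dG_bind = R T ln(Kd / 1 M),

which makes a sub-molar Kd correspond to a negative dG (e.g. 5 mM at 300 K
gives about -3.1 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_KCAL = 1.9872e-3          # gas constant, kcal/(mol K)
STANDARD_VOLUME_NM3 = 1.661  # volume per molecule at 1 M


class ProfileError(ValueError):
    pass


@dataclass
class MeanForceProfile:
    r: np.ndarray        # nm, strictly increasing
    force: np.ndarray    # kcal/(mol nm), mean force along r
    stderr: np.ndarray   # same units

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        self.force = np.asarray(self.force, float)
        self.stderr = np.asarray(self.stderr, float)
        if np.any(np.diff(self.r) <= 0):
            raise ProfileError("distance grid must be strictly increasing")
        if np.any(self.stderr < 0):
            raise ProfileError("standard errors must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "MeanForceProfile":
        """Read a 3-column TSV (r_nm, mean force, stderr); a non-numeric
        header line is skipped."""
        try:
            data = np.loadtxt(path)
        except ValueError:
            data = np.loadtxt(path, skiprows=1)
        return cls(data[:, 0], data[:, 1], data[:, 2])


@dataclass
class PMFProfile:
    r: np.ndarray
    w: np.ndarray        # kcal/mol, zero-mean over the reference window
    error: np.ndarray    # pointwise, grows away from the reference
    reference_window: tuple[float, float]

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.r, self.w, self.error]),
                   fmt="%.6g", header="r_nm\tW_kcal_mol\tstderr", comments="")


@dataclass
class BindingEstimate:
    kd: float                       # molar
    dg_bind: float                  # kcal/mol
    temperature: float              # K
    bound_window: tuple[float, float]
    minima: list[tuple[float, float]]


def integrate_mean_force(profile: MeanForceProfile,
                         reference: tuple[float, float] = (4.6, np.inf)
                         ) -> PMFProfile:
    """Trapezoid integration of the mean force into a PMF.

    W(r) = -Int_{r}^{edge} F dr integrated from the far (reference) edge,
    then shifted so the mean of W over the reference window is zero. The
    pointwise error propagates the per-segment trapezoid variances through
    that whole construction (including the re-referencing), so it is ~0 at
    the reference window and grows moving away from it.
    """
    r, f, s = profile.r, profile.force, profile.stderr
    lo, hi = reference
    in_ref = (r >= lo) & (r <= hi)
    if not np.any(in_ref):
        raise ProfileError("reference window lies outside the grid")
    # dW/dr = -F, anchored at the far edge: W(r) = Int_{r}^{rend} F dr
    dr = np.diff(r)
    seg = 0.5 * (f[1:] + f[:-1]) * dr
    cum = np.concatenate([[0.0], np.cumsum(seg)])   # Int_{r0}^{r} F dr
    w = cum[-1] - cum
    w = w - w[in_ref].mean()
    # error: w_i is linear in the (independent) force samples f_k; build the
    # per-point trapezoid coefficients of the anchored integral, apply the
    # re-referencing, and propagate the stated standard errors exactly
    # (adjacent trapezoid segments share grid points, so propagation must be
    # at the point level, not per segment)
    n = r.size
    anchored = np.zeros((n, n))          # anchored[i, k]: weight of f_k in A_i
    for i in range(n):
        if i == n - 1:
            continue
        dseg = dr[i:]
        anchored[i, i] = 0.5 * dseg[0]
        anchored[i, n - 1] = 0.5 * dseg[-1]
        if i + 1 < n - 1:
            anchored[i, i + 1:n - 1] = 0.5 * (dseg[:-1] + dseg[1:])
    ref_idx = np.flatnonzero(in_ref)
    coeff = anchored - anchored[ref_idx].mean(axis=0)
    err = np.sqrt(coeff ** 2 @ s ** 2)
    return PMFProfile(r=r.copy(), w=w, error=err,
                      reference_window=(float(lo), float(min(hi, r[-1]))))


def find_minima(pmf: PMFProfile, depth_min: float = 0.0
                ) -> list[tuple[float, float]]:
    """Local PMF minima with well depth (vs the lower flanking maximum)
    of at least ``depth_min`` kcal/mol, sorted by position."""
    w, r = pmf.w, pmf.r
    if r.size < 3:
        raise ProfileError("need at least 3 grid points")
    out = []
    for i in range(1, r.size - 1):
        if w[i] < w[i - 1] and w[i] <= w[i + 1]:
            # flanking maxima: highest point before next lower minimum
            left = w[:i].max()
            right = w[i + 1:].max()
            depth = min(left, right) - w[i]
            if depth >= depth_min and depth > 0:
                out.append((float(r[i]), float(depth)))
    return out


def kd_from_pmf(pmf: PMFProfile,
                bound_window: tuple[float, float] | None = None,
                temperature: float = 300.0,
                reference_flat_tol: float = 0.2,
                radial_jacobian: bool = True) -> BindingEstimate:
    """Standard-state Kd from the radial configurational integral.

    The bound window defaults to the grid's left edge up to the first point
    after the principal (deepest) minimum where W rises to -RT (the thermal
    boundary of the well). The reference window must be flat
    (max |W| < ``reference_flat_tol`` kcal/mol). Setting
    ``radial_jacobian=False`` drops the 4 pi r^2 volume element.
    """
    r, w = pmf.r, pmf.w
    lo, hi = pmf.reference_window
    in_ref = (r >= lo) & (r <= hi)
    if np.max(np.abs(w[in_ref])) >= reference_flat_tol:
        raise ProfileError(
            "reference window is not flat; extend the profile to larger r")
    rt = R_KCAL * temperature
    minima = find_minima(pmf)
    if bound_window is None:
        if not minima:
            raise ProfileError("no PMF minimum found; supply bound_window")
        depths = [d for _, d in minima]
        r_min = minima[int(np.argmax(depths))][0]
        after = np.flatnonzero((r > r_min) & (w >= -rt))
        if after.size:
            # locate the -RT crossing by linear interpolation so the window
            # edge does not snap to the grid spacing
            j = after[0]
            frac = (-rt - w[j - 1]) / (w[j] - w[j - 1])
            r_hi = r[j - 1] + frac * (r[j] - r[j - 1])
        else:
            r_hi = r[-1]
        bound_window = (float(r[0]), float(r_hi))
    b_lo, b_hi = bound_window
    sel = (r >= b_lo) & (r <= b_hi)
    if sel.sum() < 2:
        raise ProfileError("bound window too narrow for the grid")
    rr, ww = r[sel], w[sel]
    if b_hi < r[-1] and rr[-1] < b_hi:
        # append the interpolated window edge as a final quadrature node
        j = np.searchsorted(r, b_hi)
        frac = (b_hi - r[j - 1]) / (r[j] - r[j - 1])
        rr = np.append(rr, b_hi)
        ww = np.append(ww, w[j - 1] + frac * (w[j] - w[j - 1]))
    jac = 4.0 * np.pi * rr ** 2 if radial_jacobian else np.ones(rr.size)
    integrand = jac * np.exp(-ww / rt)
    ka = np.trapezoid(integrand, rr) / STANDARD_VOLUME_NM3
    kd = 1.0 / ka
    return BindingEstimate(kd=float(kd), dg_bind=dg_from_kd(kd, temperature),
                           temperature=temperature,
                           bound_window=(float(b_lo), float(b_hi)),
                           minima=minima)


def dg_from_kd(kd: float, temperature: float = 300.0) -> float:
    """Binding free energy (kcal/mol) from a molar Kd: dG = RT ln(Kd/1M)."""
    if kd <= 0:
        raise ProfileError("Kd must be positive")
    return float(R_KCAL * temperature * np.log(kd))


def kd_from_dg(dg_bind: float, temperature: float = 300.0) -> float:
    """Inverse of ``dg_from_kd``: Kd = exp(dG/RT) in molar."""
    return float(np.exp(dg_bind / (R_KCAL * temperature)))


def fold_ratio(estimate_a: BindingEstimate, estimate_b: BindingEstimate
               ) -> float:
    """Affinity ratio Kd(b)/Kd(a): how many fold stronger binder a is."""
    if estimate_a.temperature != estimate_b.temperature:
        raise ProfileError("estimates must share a temperature")
    return estimate_b.kd / estimate_a.kd
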