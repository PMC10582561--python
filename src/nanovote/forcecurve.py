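"""Force-curve analysis: contact detection, finite-thickness Hertz fitting,
adhesion and zero-force height extraction.

One force curve is a single indentation event: the probe approaches the
sample, touches it at the contact point, indents until a force setpoint is
reached, then retracts.  From each curve four physical channels are
extracted per pixel of a force-volume map:

``MechL``
    effective Young's modulus fitted on the shallow indentation window
    (0-30 % of the maximum indentation depth), sensitive to superficial
    cytoskeleton layers,
``MechH``
    modulus fitted on the deep window (70-100 %), sensitive to deeper
    structures but mechanically convoluted with the shallow layers,
``Adh``
    pull-off (adhesion) force, the magnitude of the retract-curve minimum
    after baseline alignment,
``Morpho``
    zero-force sample height: topography recorded at maximum force plus
    the indentation length, with the rigid substrate at height 0.

The contact model is the Hertz sphere-on-halfspace force with the
finite-thickness (bottom-effect) polynomial correction for a thin sample of
height ``h`` bonded to a rigid support::

    F = (4/3) E sqrt(R) d^{3/2} / (1 - nu^2)
        * [1 + c1*chi + c2*chi^2 + c3*chi^3 + c4*chi^4],   chi = sqrt(R d)/h

Internal unit canon: lengths in nm, forces in nN, moduli in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ProbeSpec",
    "ForceCurve",
    "ContactResult",
    "ChannelSet",
    "CORRECTION_COEFFICIENTS",
    "default_chi",
    "dimitriadis_force",
    "detect_contact_point",
    "fit_modulus",
    "extract_adhesion",
    "zero_force_height",
    "process_curve",
    "ContactDetectionError",
    "FitError",
]

# Pa * nm^2 = 1e-18 N = 1e-9 nN
_PA_NM2_TO_NN = 1e-9

#: Finite-thickness correction polynomials (chi, chi^2, chi^3, chi^4).
#: "bonded" assumes the sample is firmly attached to the substrate,
#: "free" a frictionless (free-to-slip) interface.  Adherent cells are
#: neither, so the default is the arithmetic mean of the two boundary
#: conditions as printed: (1.009, 1.032, 0.578, 0.0048).
CORRECTION_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "mean": (1.009, 1.032, 0.578, 0.0048),
    "bonded": (1.133, 1.283, 0.769, 0.0975),
    "free": (0.884, 0.781, 0.386, 0.0048),
}


class ContactDetectionError(ValueError):
    """No resolvable zero-force baseline peak in the force histogram."""


class FitError(ValueError):
    """Modulus fit failed (window too small or non-physical estimate)."""


@dataclass(frozen=True)
class ProbeSpec:
    """Spherical probe and contact-model parameters.

    Parameters
    ----------
    radius
        Probe radius R in nm (e.g. 5000 nm borosilicate sphere).
    spring_constant
        Cantilever spring constant k in N/m (e.g. 0.2).
    poisson_ratio
        Poisson ratio of the sample; 0.5 for an incompressible cell.
    """

    radius: float = 5000.0
    spring_constant: float = 0.2
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"probe radius must be positive, got {self.radius}")
        if self.spring_constant <= 0:
            raise ValueError(
                f"spring constant must be positive, got {self.spring_constant}"
            )
        if not 0.0 <= self.poisson_ratio <= 0.5 + 1e-12:
            raise ValueError(
                f"poisson ratio must lie in [0, 0.5], got {self.poisson_ratio}"
            )


@dataclass
class ForceCurve:
    """One approach/retract indentation event at a fixed lateral position.

    ``approach`` and ``retract`` are (n, 2) arrays with columns
    (piezo_displacement_nm, force_nN), both ordered by increasing
    displacement (displacement grows towards the sample).
    """

    approach: np.ndarray
    retract: np.ndarray
    pixel_index: tuple[int, int] = (0, 0)
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.approach = np.asarray(self.approach, dtype=float)
        self.retract = np.asarray(self.retract, dtype=float)
        for name, seg in (("approach", self.approach), ("retract", self.retract)):
            if seg.ndim != 2 or seg.shape[1] != 2:
                raise ValueError(f"{name} segment must be an (n, 2) array")
            if not np.all(np.isfinite(seg)):
                raise ValueError(f"{name} segment contains non-finite values")
        if len(self.approach) == 0 or len(self.retract) == 0:
            raise ValueError("both curve segments must be non-empty")
        if np.any(np.diff(self.approach[:, 0]) < 0):
            raise ValueError("approach displacement must be non-decreasing")


@dataclass(frozen=True)
class ContactResult:
    """Contact point of an approach curve.

    ``contact_index`` is the sample index of the contact point,
    ``noise_sigma`` the width of the zero-force Gaussian baseline (nN),
    ``indentation_length`` the displacement from the contact sample to the
    maximum-force sample (nm), and ``baseline_offset`` the force offset
    (nN) subtracted to align the baseline at zero.
    """

    contact_index: int
    noise_sigma: float
    indentation_length: float
    baseline_offset: float = 0.0
    #: continuous contact displacement (nm); sub-sample refinement of the
    #: contact point, equal to the contact sample's displacement when no
    #: refinement was possible
    contact_z: float = float("nan")


@dataclass(frozen=True)
class ChannelSet:
    """The four per-pixel channels extracted from one force curve."""

    MechL: float
    MechH: float
    Adh: float
    Morpho: float


def default_chi(delta: np.ndarray, radius: float, h: float) -> np.ndarray:
    """Dimensionless finite-thickness parameter chi = sqrt(R*delta)/h."""
    return np.sqrt(radius * np.asarray(delta, dtype=float)) / h


def dimitriadis_force(
    delta,
    E: float,
    h: float,
    probe: ProbeSpec,
    coefficients: str | Sequence[float] = "mean",
    chi_fn: Callable[[np.ndarray, float, float], np.ndarray] = default_chi,
):
    """Force (nN) on a sphere indenting a thin elastic layer of height ``h``.

    Hertz contact force times the finite-thickness polynomial correction;
    reduces to plain Hertz as ``h -> inf`` (chi -> 0).  Strictly increasing
    in ``delta`` and in ``E``.

    Parameters
    ----------
    delta
        Indentation depth in nm, scalar or array, >= 0.
    E
        Effective Young's modulus in Pa.
    h
        Local sample height (probe-to-substrate layer thickness) in nm; > 0.
    coefficients
        Name from :data:`CORRECTION_COEFFICIENTS` or an explicit 4-sequence.
    chi_fn
        The chi definition; swappable for sensitivity studies.
    """
    if h <= 0:
        raise ValueError(f"sample height h must be positive, got {h}")
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation delta must be non-negative")
    if isinstance(coefficients, str):
        c1, c2, c3, c4 = CORRECTION_COEFFICIENTS[coefficients]
    else:
        c1, c2, c3, c4 = coefficients
    chi = chi_fn(d, probe.radius, h)
    correction = 1.0 + c1 * chi + c2 * chi**2 + c3 * chi**3 + c4 * chi**4
    hertz = (
        (4.0 / 3.0)
        * E
        * np.sqrt(probe.radius)
        * d**1.5
        / (1.0 - probe.poisson_ratio**2)
    ) * _PA_NM2_TO_NN
    out = hertz * correction
    return float(out) if np.isscalar(delta) else out


def _baseline_gaussian(
    forces: np.ndarray, n_bins: int, min_peak_fraction: float
) -> tuple[float, float]:
    """Locate the zero-force baseline as the dominant histogram peak.

    Returns (mean, sigma) of the Gaussian-like peak.  Raises
    :class:`ContactDetectionError` when no bin neighbourhood concentrates
    enough samples to qualify as a baseline (e.g. an all-contact curve).
    """
    lo, hi = float(np.min(forces)), float(np.max(forces))
    if hi - lo <= 0:
        # perfectly constant segment: all baseline
        return lo, 0.0
    counts, edges = np.histogram(forces, bins=n_bins, range=(lo, hi))
    peak = int(np.argmax(counts))
    sel = (forces >= edges[max(peak - 1, 0)]) & (
        forces <= edges[min(peak + 2, n_bins)]
    )
    if sel.sum() < min_peak_fraction * len(forces):
        raise ContactDetectionError(
            "no resolvable zero-force peak in the force histogram"
        )
    mu = float(np.mean(forces[sel]))
    sigma = float(np.std(forces[sel]))
    # iterative 4-sigma clipping: the peak-bin neighbourhood is much wider
    # than the baseline width, so the first-pass sigma is contaminated by
    # early-contact samples
    for _ in range(10):
        if sigma <= 0:
            break
        sel = np.abs(forces - mu) <= 4.0 * sigma
        new_mu = float(np.mean(forces[sel]))
        new_sigma = float(np.std(forces[sel]))
        converged = new_sigma >= 0.99 * sigma
        mu, sigma = new_mu, new_sigma
        if converged:
            break
    return mu, sigma


def _refine_extrapolation(
    z: np.ndarray, f: np.ndarray, win: np.ndarray
) -> float | None:
    """Sub-threshold contact refinement without a contact model.

    Fits a quadratic to F^(2/3) over the gentle-onset window (valid because
    F grows as delta^(3/2) near contact, with mild curvature from the
    finite-thickness correction) and extrapolates to zero force.
    """
    x, y = z[win], f[win] ** (2.0 / 3.0)
    coef = np.polyfit(x, y, 2)
    roots = np.roots(coef)
    roots = roots[np.isreal(roots)].real
    roots = roots[roots <= x[0]]
    if len(roots):
        return float(roots[np.argmin(np.abs(roots - x[0]))])
    slope, intercept = np.polyfit(x, y, 1)
    return float(-intercept / slope) if slope > 0 else None


def _profile_modulus(
    x: np.ndarray, y: np.ndarray, z0: float, probe: ProbeSpec,
    reference_altitude: float, coefficients: str | Sequence[float],
) -> float:
    """Closed-form least-squares E for a fixed candidate contact z0."""
    d = np.clip(x - z0, 0.0, None)
    m = dimitriadis_force(d, 1.0, reference_altitude - z0, probe, coefficients)
    mm = float(np.dot(m, m))
    return max(float(np.dot(m, y)) / max(mm, 1e-300), 0.0)


def _refine_profile(
    z: np.ndarray,
    f: np.ndarray,
    win: np.ndarray,
    crossing: int,
    probe: ProbeSpec,
    reference_altitude: float,
    coefficients: str | Sequence[float],
    span: float = 200.0,
    step: float = 2.0,
    n_baseline: int = 25,
) -> float | None:
    """Model-matched contact refinement by profiled least squares.

    For each candidate contact position z0 on a fine grid, the local
    height is h = reference_altitude - z0, the modulus that best fits the
    early-contact force is computed in closed form (the model is linear in
    E), and the candidate with the smallest residual wins.  Baseline
    samples just before the crossing are included so that too-early
    candidates are penalised.
    """
    lo = np.arange(max(crossing - n_baseline, 0), crossing)
    sel = np.concatenate([lo, win])
    x, y = z[sel], f[sel]
    zc = z[crossing]

    def profile_sse(cands: np.ndarray) -> np.ndarray:
        d = np.clip(x[None, :] - cands[:, None], 0.0, None)
        h = (reference_altitude - cands)[:, None]
        m = dimitriadis_force(d, 1.0, 1.0, probe, coefficients,
                              chi_fn=lambda dd, R, _h: np.sqrt(R * dd) / h)
        mm = np.einsum("ij,ij->i", m, m)
        fm = m @ y
        E = np.clip(fm / np.maximum(mm, 1e-300), 0.0, None)
        return np.dot(y, y) - 2.0 * E * fm + E**2 * mm

    z0 = float(zc)
    for st in (step, step / 8.0):  # coarse pass, then fine pass around min
        z_lo = max(z0 - span if st == step else z0 - 2.0 * step, 1e-9)
        z_hi = min(z0 + 2.0 * st if st == step else z0 + 2.0 * step,
                   reference_altitude - 1.0)
        cands = np.arange(z_lo, z_hi, st)
        cands = cands[reference_altitude - cands > 1.0]
        if len(cands) == 0:
            return None
        sse = profile_sse(cands)
        k = int(np.argmin(sse))
        z0 = float(cands[k])
        if 0 < k < len(cands) - 1:
            # parabolic interpolation of the residual minimum
            s0, s1, s2 = sse[k - 1], sse[k], sse[k + 1]
            denom = s0 - 2.0 * s1 + s2
            if denom > 0:
                z0 += 0.5 * st * (s0 - s2) / denom
    return z0


def detect_contact_point(
    curve: ForceCurve,
    n_bins: int = 64,
    threshold_sigma: float = 2.0,
    min_peak_fraction: float = 0.25,
    refine: bool = True,
    probe: ProbeSpec | None = None,
    reference_altitude: float | None = None,
    coefficients: str | Sequence[float] = "mean",
) -> ContactResult:
    """Locate the contact point of the approach segment.

    The non-contact baseline is identified as the dominant, sharply defined
    peak of the force histogram; after subtracting its mean, the initial
    contact estimate is the first sample (before maximum force) whose force
    exceeds ``threshold_sigma`` times the peak width.  A Hertz-like onset
    crosses that threshold several samples late, so the estimate is then
    refined below the threshold: by a profiled least-squares search with
    the thickness-corrected contact model when ``probe`` and
    ``reference_altitude`` are given (map processing), otherwise by
    quadratic extrapolation of F^(2/3) to zero force.

    Raises
    ------
    ContactDetectionError
        If the histogram shows no baseline peak (all-contact curve), or the
        curve never leaves the baseline.
    """
    z = curve.approach[:, 0]
    f_raw = curve.approach[:, 1]
    mu, sigma = _baseline_gaussian(f_raw, n_bins, min_peak_fraction)
    f = f_raw - mu
    sigma_eff = max(sigma, 1e-12)

    imax = int(np.argmax(f))
    threshold = threshold_sigma * sigma_eff
    if f[imax] <= threshold:
        raise ContactDetectionError("approach curve never leaves the baseline")
    below = np.nonzero(f[: imax + 1] <= threshold)[0]
    contact = min(int(below[-1]) + 1, imax) if len(below) else 0
    contact_z = float(z[contact])

    if refine and contact < imax:
        fmax = f[imax]
        first_cap = 0.05 if reference_altitude is not None else 0.1
        cap = max(first_cap * fmax, 5.0 * threshold)
        win = np.nonzero((f > threshold) & (f <= cap))[0]
        win = win[(win >= contact) & (win <= imax)]
        if len(win) >= 5:
            if reference_altitude is not None:
                probe = probe or ProbeSpec()
                z0 = _refine_profile(
                    z, f, win, contact, probe, reference_altitude, coefficients,
                )
                if z0 is not None:
                    # widen the window as far as the curve stays consistent
                    # with one effective modulus (a stiffer deep layer would
                    # otherwise bias the contact estimate) and re-profile
                    E0 = _profile_modulus(z[win], f[win], z0, probe,
                                          reference_altitude, coefficients)
                    ext = np.nonzero((f > threshold) & (f <= 0.3 * fmax))[0]
                    ext = ext[(ext >= contact) & (ext <= imax)]
                    pred = dimitriadis_force(
                        np.clip(z[ext] - z0, 0.0, None), E0,
                        max(reference_altitude - z0, 1.0), probe, coefficients,
                    )
                    tol = np.maximum(5.0 * sigma_eff, 0.05 * pred)
                    bad = np.nonzero(np.abs(f[ext] - pred) > tol)[0]
                    ext = ext[: bad[0]] if len(bad) else ext
                    if len(ext) > len(win):
                        z0 = _refine_profile(
                            z, f, ext, contact, probe, reference_altitude,
                            coefficients,
                        ) or z0
            else:
                z0 = _refine_extrapolation(z, f, win)
            if z0 is not None and z0 <= contact_z:
                contact_z = float(z0)
                contact = int(np.argmin(np.abs(z - z0)))

    indentation = float(z[imax] - contact_z)
    return ContactResult(
        contact_index=contact,
        noise_sigma=sigma_eff,
        indentation_length=max(indentation, 0.0),
        baseline_offset=mu,
        contact_z=contact_z,
    )


def fit_modulus(
    curve: ForceCurve,
    contact: ContactResult,
    fraction_range: tuple[float, float],
    h: float,
    probe: ProbeSpec,
    coefficients: str | Sequence[float] = "mean",
    min_samples: int = 5,
) -> float:
    """Least-squares effective Young's modulus (Pa) on an indentation window.

    The window ``fraction_range = (a, b)`` selects approach samples whose
    indentation lies in [a*dmax, b*dmax] of the maximum depth dmax;
    (0, 0.30) yields the shallow channel MechL and (0.70, 1.00) the deep
    channel MechH.  The contact model is linear in E, so the least-squares
    minimiser is computed in closed form.

    Raises
    ------
    FitError
        Fewer than ``min_samples`` samples in the window, or E <= 0.
    """
    a, b = fraction_range
    if not (0.0 <= a < b <= 1.0):
        raise ValueError(f"fraction_range must satisfy 0 <= a < b <= 1, got {a, b}")
    z = curve.approach[:, 0]
    f = curve.approach[:, 1] - contact.baseline_offset
    dmax = contact.indentation_length
    if dmax <= 0:
        raise FitError("zero indentation length")
    z0 = contact.contact_z if np.isfinite(contact.contact_z) else z[contact.contact_index]
    delta = z - z0
    sel = (delta >= a * dmax) & (delta <= b * dmax) & (delta > 0)
    if sel.sum() < min_samples:
        raise FitError(
            f"only {int(sel.sum())} samples in indentation window [{a}, {b}]"
        )
    model = dimitriadis_force(delta[sel], 1.0, h, probe, coefficients)
    denom = float(np.dot(model, model))
    if denom <= 0:
        raise FitError("degenerate model column in modulus fit")
    E = float(np.dot(f[sel], model) / denom)
    if E <= 0 or not np.isfinite(E):
        raise FitError(f"non-physical modulus estimate {E}")
    return E


def extract_adhesion(
    curve: ForceCurve,
    contact: ContactResult | None = None,
    n_bins: int = 64,
    min_peak_fraction: float = 0.25,
) -> float:
    """Adhesion force (nN, >= 0): magnitude of the retract-curve minimum
    after zero-force alignment of the retract baseline.

    A reversible curve (retract identical to approach, no pull-off well)
    yields 0 up to baseline noise.
    """
    f_raw = curve.retract[:, 1]
    mu, _ = _baseline_gaussian(f_raw, n_bins, min_peak_fraction)
    return max(0.0, -float(np.min(f_raw - mu)))


def zero_force_height(height_at_max_force: float, contact: ContactResult) -> float:
    """Zero-force (Morpho) height in nm.

    Topography is recorded at maximum force, i.e. with the sample
    compressed by the indentation length; adding the indentation back gives
    the undeformed surface height.  Substrate pixels (no indentation,
    recorded height 0) map to ~0; small negative noise residues clip to 0.
    """
    return max(0.0, height_at_max_force + contact.indentation_length)


def process_curve(
    curve: ForceCurve,
    probe: ProbeSpec,
    reference_altitude: float,
    n_bins: int = 64,
    threshold_sigma: float = 2.0,
    shallow_window: tuple[float, float] = (0.0, 0.30),
    deep_window: tuple[float, float] = (0.70, 1.00),
    coefficients: str | Sequence[float] = "mean",
) -> ChannelSet:
    """Extract all four channels from one curve.

    ``reference_altitude`` is the probe altitude above the substrate at
    zero piezo extension (shared by all pixels of a map); the recorded
    height at maximum force is ``reference_altitude - z(max force)``.
    The local height used by the finite-thickness correction is the
    pixel's own zero-force height.

    Raises :class:`ContactDetectionError` or :class:`FitError`; callers
    building maps catch these and flag the pixel invalid.
    """
    contact = detect_contact_point(
        curve,
        n_bins=n_bins,
        threshold_sigma=threshold_sigma,
        probe=probe,
        reference_altitude=reference_altitude,
        coefficients=coefficients,
    )
    z = curve.approach[:, 0]
    imax = int(np.argmax(curve.approach[:, 1] - contact.baseline_offset))
    height_at_max = reference_altitude - float(z[imax])
    morpho = zero_force_height(height_at_max, contact)
    h_local = max(morpho, 1.0)  # 1 nm floor keeps the model defined
    mech_l = fit_modulus(curve, contact, shallow_window, h_local, probe, coefficients)
    mech_h = fit_modulus(curve, contact, deep_window, h_local, probe, coefficients)
    adh = extract_adhesion(curve, contact, n_bins=n_bins)
    return ChannelSet(MechL=mech_l, MechH=mech_h, Adh=adh, Morpho=morpho)


def process_map(
    curves: Sequence[ForceCurve],
    grid_shape: tuple[int, int],
    probe: ProbeSpec,
    reference_altitude: float,
    **kwargs,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Extract the four channel maps from a grid of force curves.

    Returns ``(channels, valid)`` where ``channels`` maps channel name to a
    2D array (invalid pixels set to 0; Morpho keeps the substrate-at-0
    convention) and ``valid`` marks pixels where every channel was
    extracted.  Pixels whose contact detection or modulus fit fails are
    flagged invalid, as are grid positions with no curve (e.g. setpoint
    never reached).  Keyword arguments are passed to :func:`process_curve`.
    """
    channels = {k: np.zeros(grid_shape) for k in ("Adh", "MechH", "MechL", "Morpho")}
    valid = np.zeros(grid_shape, dtype=bool)
    for curve in curves:
        r, c = curve.pixel_index
        try:
            cs = process_curve(curve, probe, reference_altitude, **kwargs)
        except (ContactDetectionError, FitError):
            continue
        channels["Adh"][r, c] = cs.Adh
        channels["MechH"][r, c] = cs.MechH
        channels["MechL"][r, c] = cs.MechL
        channels["Morpho"][r, c] = cs.Morpho
        valid[r, c] = True
    return channels, valid
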