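"""Synthetic three-phenotype force-volume generator.

Emulates force-volume maps of single adherent macrophages on a rigid flat
substrate, in the three classical polarization states:

* ``M0`` (resting): round dome, soft (baseline modulus ~150 Pa).
* ``M1`` (pro-inflammatory): swollen footprint, rounder and flatter,
  markedly stiffer.
* ``M2`` (pro-healing): smaller, elongated footprint, slightly stiffer
  than M0 with pronounced periphery stiffening.

Adhesion is drawn from the same distribution for all three phenotypes
(non-functionalised probe), so it carries no class signal by construction.

Each cell is a 32x32 grid of ground-truth fields (height, shallow and deep
modulus, adhesion) from which raw approach/retract force curves are
forward-generated with the finite-thickness Hertz model plus additive
Gaussian force noise, so the whole analysis pipeline can be exercised and
checked against generation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .forcecurve import ForceCurve, ProbeSpec, dimitriadis_force

__all__ = [
    "PhenotypeProfile",
    "SyntheticCell",
    "AcquisitionSpec",
    "DEFAULT_PROFILES",
    "HARD_PROFILES",
    "PHENOTYPES",
    "blended_modulus",
    "generate_cell",
    "synthesize_force_curve",
    "synthesize_map_curves",
    "generate_dataset",
    "SetpointUnreachableError",
]

PHENOTYPES = ("M0", "M1", "M2")


class SetpointUnreachableError(RuntimeError):
    """The force setpoint cannot be reached within the ramp size."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Ramp parameters shared by all curves of a map.

    ``reference_altitude`` is the probe altitude (nm) above the substrate
    at zero piezo extension; it must exceed the tallest cell and stay
    below ``ramp_size`` so the substrate itself is reachable.
    """

    ramp_size: float = 8000.0
    setpoint: float = 7.0
    samples_per_segment: int = 512
    rate: float = 2.0
    reference_altitude: float = 6500.0
    noise_sigma: float = 0.01


@dataclass(frozen=True)
class PhenotypeProfile:
    """Morphological and mechanical population parameters of one phenotype.

    Lengths in nm (heights) or pixels (footprint semi-axes); moduli in Pa;
    adhesion in nN.  ``periphery_multiplier`` scales the shallow modulus
    from the cell centre (x1) to the rim; ``modulus_noise_sd`` is the
    sigma of multiplicative lognormal spatial noise; ``deep_ratio`` sets
    E_deep = deep_ratio * E_shallow.
    """

    name: str
    semi_axes: tuple[float, float]
    max_height: float
    modulus: float
    deep_ratio: float = 2.0
    periphery_multiplier: float = 1.3
    modulus_noise_sd: float = 0.25
    adhesion_mean: float = 0.30
    adhesion_sd: float = 0.06
    axis_jitter: float = 0.12
    height_exponent: float = 1.5


#: Default study populations.  Contrasts: M1 much stiffer, larger and
#: flatter than M0; M2 smaller, elongated, slightly stiffer with strong
#: periphery enhancement; adhesion identical across phenotypes.
DEFAULT_PROFILES: dict[str, PhenotypeProfile] = {
    "M0": PhenotypeProfile(
        name="M0", semi_axes=(9.0, 8.0), max_height=5000.0, modulus=150.0,
        periphery_multiplier=1.3,
    ),
    "M1": PhenotypeProfile(
        name="M1", semi_axes=(13.0, 12.0), max_height=3500.0, modulus=600.0,
        periphery_multiplier=1.5,
    ),
    "M2": PhenotypeProfile(
        name="M2", semi_axes=(11.0, 4.5), max_height=4000.0, modulus=250.0,
        periphery_multiplier=1.8,
    ),
}

#: Overlapping-modulus populations to exercise misclassification paths.
HARD_PROFILES: dict[str, PhenotypeProfile] = {
    "M0": PhenotypeProfile(
        name="M0", semi_axes=(9.0, 8.0), max_height=5000.0, modulus=180.0,
        modulus_noise_sd=0.45, periphery_multiplier=1.3,
    ),
    "M1": PhenotypeProfile(
        name="M1", semi_axes=(11.0, 10.0), max_height=4200.0, modulus=260.0,
        modulus_noise_sd=0.45, periphery_multiplier=1.4,
    ),
    "M2": PhenotypeProfile(
        name="M2", semi_axes=(10.0, 6.0), max_height=4500.0, modulus=220.0,
        modulus_noise_sd=0.45, periphery_multiplier=1.5,
    ),
}


@dataclass
class SyntheticCell:
    """Ground-truth maps of one synthetic cell on a ``grid`` x ``grid`` map.

    ``height`` is exactly 0 outside the cell footprint (rigid substrate).
    """

    height: np.ndarray
    e_shallow: np.ndarray
    e_deep: np.ndarray
    adhesion: np.ndarray
    label: str
    seed: int
    cell_id: str = ""

    @property
    def footprint(self) -> np.ndarray:
        return self.height > 0


def generate_cell(
    phenotype: str,
    grid: int = 32,
    seed: int = 0,
    profiles: dict[str, PhenotypeProfile] | None = None,
) -> SyntheticCell:
    """Draw one synthetic cell of the given phenotype.

    The height field is a smooth dome ``h = H (1 - rho^2)^q`` over a
    randomly oriented, jittered elliptical footprint; shallow modulus is
    baseline x periphery factor x lognormal spatial noise, deep modulus a
    fixed multiple of it; adhesion is i.i.d. normal truncated at 0.05 nN.
    Deterministic given ``seed``.
    """
    profiles = profiles or DEFAULT_PROFILES
    prof = profiles[phenotype]
    rng = np.random.default_rng(seed)

    a = prof.semi_axes[0] * rng.normal(1.0, prof.axis_jitter)
    b = prof.semi_axes[1] * rng.normal(1.0, prof.axis_jitter)
    a, b = max(a, 2.0), max(b, 2.0)
    theta = rng.uniform(0.0, np.pi)
    margin = 2.0
    cmax = max(a, b)
    lo = cmax + margin
    hi = grid - 1 - cmax - margin
    if hi <= lo:
        center = np.array([(grid - 1) / 2.0] * 2)
    else:
        center = rng.uniform(lo, hi, size=2)

    rows, cols = np.mgrid[0:grid, 0:grid].astype(float)
    dr, dc = rows - center[0], cols - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    inside = rho2 < 1.0
    height = np.zeros((grid, grid))
    height[inside] = prof.max_height * (1.0 - rho2[inside]) ** prof.height_exponent

    rho = np.sqrt(np.clip(rho2, 0.0, 1.0))
    periphery = 1.0 + (prof.periphery_multiplier - 1.0) * rho**2
    noise = rng.lognormal(mean=0.0, sigma=prof.modulus_noise_sd, size=(grid, grid))
    e_shallow = np.where(inside, prof.modulus * periphery * noise, 0.0)
    e_deep = e_shallow * prof.deep_ratio
    adhesion = np.clip(
        rng.normal(prof.adhesion_mean, prof.adhesion_sd, size=(grid, grid)), 0.05, None
    )
    return SyntheticCell(
        height=height,
        e_shallow=e_shallow,
        e_deep=e_deep,
        adhesion=adhesion,
        label=phenotype,
        seed=seed,
    )


def blended_modulus(
    fraction: np.ndarray, e_shallow: float, e_deep: float, blend_start: float = 0.5
):
    """Depth-dependent modulus of the two-layer forward model.

    Equal to ``e_shallow`` for indentation fractions below ``blend_start``
    of the final depth, then blending linearly to ``e_deep`` at full depth.
    """
    f = np.asarray(fraction, dtype=float)
    t = np.clip((f - blend_start) / (1.0 - blend_start), 0.0, 1.0)
    return e_shallow + (e_deep - e_shallow) * t


_SUBSTRATE_E = 2.0e9  # Pa; glass-like, indents < 0.1 nm at 7 nN
_WALL_SLOPE = 5.0  # nN/nm hard-wall slope when the probe bottoms out


def _two_layer_force(
    delta: np.ndarray,
    delta_max: float,
    e_shallow: float,
    e_deep: float,
    h: float,
    probe: ProbeSpec,
    blend_start: float,
) -> np.ndarray:
    E = blended_modulus(np.asarray(delta) / delta_max, e_shallow, e_deep, blend_start)
    return dimitriadis_force(delta, 1.0, h, probe) * E


def _solve_max_indentation(
    e_shallow: float,
    e_deep: float,
    h: float,
    probe: ProbeSpec,
    setpoint: float,
    blend_start: float,
) -> tuple[float, float]:
    """Depth at which the setpoint is reached, plus any hard-wall force gap.

    The soft layer cannot be indented past ~95 % of its height; if the
    setpoint is not reached by then (thin soft periphery), the remainder is
    taken up by a stiff linear wall against the substrate.
    """
    cap = 0.95 * h

    def g(d: float) -> float:
        return float(
            _two_layer_force(d, d, e_shallow, e_deep, h, probe, blend_start)
        ) - setpoint

    if g(cap) <= 0:
        return cap, setpoint - (g(cap) + setpoint)
    d = brentq(g, 1e-6, cap, xtol=1e-4)
    return float(d), 0.0


def synthesize_force_curve(
    height: float,
    e_shallow: float,
    e_deep: float,
    adhesion: float,
    probe: ProbeSpec,
    acq: AcquisitionSpec,
    rng: np.random.Generator,
    pixel_index: tuple[int, int] = (0, 0),
    blend_start: float = 0.5,
    pulloff_width: float = 150.0,
) -> ForceCurve:
    """Forward-generate one approach/retract curve from pixel ground truth.

    The approach is zero force until contact at piezo extension
    ``reference_altitude - height``, then the two-layer finite-thickness
    Hertz force up to the setpoint; the retract mirrors the approach with a
    Gaussian pull-off well of depth ``adhesion`` centred at the contact
    point.  Additive i.i.d. Gaussian noise of width ``acq.noise_sigma`` is
    applied to both segments.  Substrate pixels (height 0) contact a
    glass-like halfspace.

    Raises
    ------
    SetpointUnreachableError
        If the setpoint is not reached within the ramp size (flagged pixel).
    """
    if height > 0:
        z_contact = acq.reference_altitude - height
        if z_contact <= 0:
            raise SetpointUnreachableError("cell taller than reference altitude")
        d_max, wall_gap = _solve_max_indentation(
            e_shallow, e_deep, height, probe, acq.setpoint, blend_start
        )
    else:
        z_contact = acq.reference_altitude
        hertz1 = dimitriadis_force(1.0, _SUBSTRATE_E, 1e9, probe)
        d_max = (acq.setpoint / hertz1) ** (2.0 / 3.0)
        wall_gap = 0.0

    z_wall = wall_gap / _WALL_SLOPE if wall_gap > 0 else 0.0
    z_max = z_contact + d_max + z_wall
    if z_max > acq.ramp_size:
        raise SetpointUnreachableError(
            f"setpoint requires extension {z_max:.0f} nm > ramp {acq.ramp_size:.0f} nm"
        )

    n = acq.samples_per_segment
    z = np.linspace(0.0, z_max, n)
    force = np.zeros(n)
    in_contact = z > z_contact
    delta = np.clip(z - z_contact, 0.0, d_max)
    if height > 0:
        force[in_contact] = _two_layer_force(
            delta[in_contact], d_max, e_shallow, e_deep, height, probe, blend_start
        )
    else:
        force[in_contact] = dimitriadis_force(
            delta[in_contact], _SUBSTRATE_E, 1e9, probe
        )
    if z_wall > 0:
        wall = z > z_contact + d_max
        force[wall] += _WALL_SLOPE * (z[wall] - z_contact - d_max)

    retract = force.copy()
    pre = z <= z_contact
    retract[pre] = -adhesion * np.exp(
        -(((z_contact - z[pre]) / pulloff_width) ** 2)
    )

    if acq.noise_sigma > 0:
        force = force + rng.normal(0.0, acq.noise_sigma, n)
        retract = retract + rng.normal(0.0, acq.noise_sigma, n)

    meta = {"ramp_size": acq.ramp_size, "setpoint": acq.setpoint, "rate": acq.rate}
    return ForceCurve(
        approach=np.column_stack([z, force]),
        retract=np.column_stack([z, retract]),
        pixel_index=pixel_index,
        acquisition=meta,
    )


def synthesize_map_curves(
    cell: SyntheticCell,
    probe: ProbeSpec | None = None,
    acq: AcquisitionSpec | None = None,
    seed: int | None = None,
) -> tuple[list[ForceCurve], np.ndarray]:
    """Generate the full grid of curves for one cell.

    Returns the curve list (row-major) and a boolean ``flagged`` grid
    marking pixels whose setpoint was unreachable (curve omitted).
    """
    probe = probe or ProbeSpec()
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(cell.seed + 1 if seed is None else seed)
    grid = cell.height.shape[0]
    curves: list[ForceCurve] = []
    flagged = np.zeros_like(cell.height, dtype=bool)
    for r in range(grid):
        for c in range(grid):
            try:
                curves.append(
                    synthesize_force_curve(
                        float(cell.height[r, c]),
                        float(cell.e_shallow[r, c]),
                        float(cell.e_deep[r, c]),
                        float(cell.adhesion[r, c]),
                        probe,
                        acq,
                        rng,
                        pixel_index=(r, c),
                    )
                )
            except SetpointUnreachableError:
                flagged[r, c] = True
    return curves, flagged


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    grid: int = 32,
    profiles: dict[str, PhenotypeProfile] | None = None,
) -> tuple[list[SyntheticCell], dict]:
    """Balanced labelled collection of synthetic cells plus a manifest.

    Per-cell seeds are derived from ``seed`` and recorded in the manifest
    so any cell can be regenerated exactly.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    profiles = profiles or DEFAULT_PROFILES
    root = np.random.default_rng(seed)
    cells: list[SyntheticCell] = []
    manifest: dict = {"seed": seed, "grid": grid, "cells": [],
                      "profiles": {k: asdict(v) for k, v in profiles.items()}}
    for label in PHENOTYPES:
        for i in range(n_per_class):
            cell_seed = int(root.integers(0, 2**31 - 1))
            cell = generate_cell(label, grid=grid, seed=cell_seed, profiles=profiles)
            cell.cell_id = f"{label}_{i:03d}"
            cells.append(cell)
            manifest["cells"].append(
                {"cell_id": cell.cell_id, "label": label, "seed": cell_seed}
            )
    return cells, manifest
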