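"""Electrode montages and an analytic three-shell spherical forward model.

The forward problem of EEG maps cortical current dipoles to scalp potentials,
``y = M x + eps``, where ``M`` is the lead field (gain) matrix.  This module
builds the three ingredients of ``M`` on an idealized spherical head:

* :func:`build_montage` places the electrodes of the international 10-05 /
  10-10 systems on the scalp sphere by the classical proportional-arc
  construction (nasion, inion and the preauricular points as fiducials),
* :func:`build_source_space` distributes fixed, radially oriented dipoles
  quasi-uniformly over a bilateral cortical shell,
* :func:`forward_gain` evaluates the potential of each unit dipole at each
  electrode with the multilayer concentric-sphere Legendre expansion
  (brain / skull / scalp compartments), in the average-reference convention.

The spherical model preserves the volume-conduction structure (skull
attenuation and spatial blurring) that source-imaging benchmarks need while
requiring no subject anatomy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Montage",
    "SourceSpace",
    "ShellModel",
    "LeadField",
    "build_montage",
    "build_source_space",
    "forward_gain",
    "label_side",
    "mirror_label",
]

GOLDEN_FRAC = (np.sqrt(5.0) - 1.0) / 2.0

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|10h?|[1-9]h?)$")


def parse_label(label: str) -> tuple[str, str]:
    """Split an extended 10-20 label into (row prefix, lateral designator).

    The designator is ``'z'`` for midline electrodes or a digit string with an
    optional ``'h'`` (half-step) suffix, e.g. ``'C3h' -> ('C', '3h')``.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"label {label!r} does not follow 10-20 nomenclature")
    return m.group(1), m.group(2)


def label_side(label: str) -> str:
    """Return 'L', 'R' or 'M' (midline) from 10-20 digit parity (odd=left)."""
    _, d = parse_label(label)
    if d == "z":
        return "M"
    return "L" if int(d.rstrip("h")) % 2 == 1 else "R"


def mirror_label(label: str) -> str:
    """Label of the homologous electrode in the opposite hemisphere.

    Odd digits (left) map to the next even digit and vice versa; midline
    labels are fixed points (``'C3' -> 'C4'``, ``'Cz' -> 'Cz'``).
    """
    prefix, d = parse_label(label)
    if d == "z":
        return label
    half = d.endswith("h")
    num = int(d.rstrip("h"))
    num = num + 1 if num % 2 == 1 else num - 1
    return f"{prefix}{num}{'h' if half else ''}"


class ConfigurationError(ValueError):
    """Invalid montage/model configuration."""


class DomainError(ValueError):
    """Geometry outside the model's domain of validity."""


@dataclass(frozen=True)
class Montage:
    """Named electrode positions on the scalp sphere.

    positions are in meters, all at radius ``scalp_radius`` from the head
    center; ``system`` tags the placement scheme.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) meters
    system: str = "custom"

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise ConfigurationError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ConfigurationError("positions must be (n_labels, 3)")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.positions[0]))

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels, system: str = "custom") -> "Montage":
        """Sub-montage restricted to ``labels``, keeping this montage's order."""
        keep = set(labels)
        missing = keep - set(self.labels)
        if missing:
            raise ConfigurationError(f"labels not in montage: {sorted(missing)}")
        idx = [i for i, l in enumerate(self.labels) if l in keep]
        return Montage(
            tuple(self.labels[i] for i in idx), self.positions[idx], system
        )


@dataclass(frozen=True)
class SourceSpace:
    """Bilateral cortical source shell with fixed radial orientations."""

    positions: np.ndarray  # (n, 3) meters
    orientations: np.ndarray  # (n, 3) unit vectors
    hemisphere: np.ndarray  # (n,) 'L'/'R'
    n_per_hemisphere: int

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class ShellModel:
    """Three concentric conducting shells: brain, skull, scalp.

    radii are the outer radii of each compartment in meters (ascending);
    conductivities in S/m follow the same order.  ``series_terms`` truncates
    the Legendre expansion of the potential; see :func:`forward_gain`.
    """

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.3, 0.006, 0.3)
    series_terms: int = 100

    def __post_init__(self):
        r = np.asarray(self.radii, float)
        s = np.asarray(self.conductivities, float)
        if r.shape != (3,) or not np.all(np.diff(r) > 0):
            raise ConfigurationError("radii must be 3 strictly increasing values")
        if s.shape != (3,) or not np.all(s > 0):
            raise ConfigurationError("conductivities must be 3 positive values")
        if self.series_terms < 20:
            raise ConfigurationError("series_terms must be at least 20")


@dataclass(frozen=True)
class LeadField:
    """Gain matrix [n_channels x n_sources] with its montage and source space."""

    gain: np.ndarray
    montage: Montage
    source_space: SourceSpace
    shell: ShellModel | None = None

    def __post_init__(self):
        g = np.asarray(self.gain, float)
        if not np.all(np.isfinite(g)):
            raise ValueError("lead field contains non-finite entries")
        if g.shape != (len(self.montage), len(self.source_space)):
            raise ValueError("gain shape does not match montage/source space")
        object.__setattr__(self, "gain", g)

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


# ---------------------------------------------------------------------------
# Montage construction
# ---------------------------------------------------------------------------

def _sph(radius: float, polar_deg, azim_deg) -> np.ndarray:
    """Point on the sphere; polar angle from the vertex, azimuth from the
    anterior midline, positive toward the right ear (x right, y front, z up)."""
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azim_deg)
    return radius * np.array(
        [np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)]
    )


def _circumcenter(a, b, c):
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    n2 = np.dot(n, n)
    return a + (
        np.dot(ac, ac) * np.cross(n, ab) + np.dot(ab, ab) * np.cross(ac, n)
    ) / (2.0 * n2)


def _arc_point(mid, end, frac):
    """Point at ``frac`` of the circular arc from ``mid`` to ``end``.

    The arc lies on the circle through mid and end centred at the
    circumcenter of (mid, end, mirror-of-end); both endpoints are on the
    scalp sphere, so every interpolated point is too.
    """
    mirror = end * np.array([-1.0, 1.0, 1.0])
    center = _circumcenter(mid, end, mirror)
    v, w = mid - center, end - center
    axis = np.cross(v, w)
    norm = np.linalg.norm(axis)
    if norm < 1e-15:  # mid == end direction; degenerate
        return mid.copy()
    axis /= norm
    ang = frac * np.arctan2(norm, np.dot(v, w))
    # Rodrigues rotation of v about axis
    rot = (
        v * np.cos(ang)
        + np.cross(axis, v) * np.sin(ang)
        + axis * np.dot(axis, v) * (1.0 - np.cos(ang))
    )
    return center + rot


# lateral slot -> digit string for the left side; right side adds 1.
_SLOT_DIGIT_L = {1: "1h", 2: "1", 3: "3h", 4: "3", 5: "5h", 6: "5", 7: "7h", 8: "7", 9: "9h", 10: "9"}
_SLOT_DIGIT_R = {1: "2h", 2: "2", 3: "4h", 4: "4", 5: "6h", 6: "6", 7: "8h", 8: "8", 9: "10h", 10: "10"}

# rows spanning the full lateral extent under a single prefix
_FULL_ROWS = [("AFp", 0.15), ("AF", 0.20), ("AFF", 0.25), ("F", 0.30),
              ("P", 0.70), ("PPO", 0.75), ("PO", 0.80), ("POO", 0.85)]
# central band rows whose temporal extension (slots >= 7) is renamed
_CENTRAL_ROWS = [("FFC", "FFT", 0.35), ("FC", "FT", 0.40), ("FCC", "FTT", 0.45),
                 ("C", "T", 0.50), ("CCP", "TTP", 0.55), ("CP", "TP", 0.60),
                 ("CPP", "TPP", 0.65)]

_LEGACY_SYNONYMS = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

#: the classical 72-electrode 10-10 chart (a label subset of the 10-05 set)
TEN10_LABELS = (
    ["Fpz", "Fp1", "Fp2", "AFz", "AF3", "AF4", "AF7", "AF8"]
    + [f"F{d}" for d in ["z", 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]]
    + [f"FC{d}" for d in ["z", 1, 2, 3, 4, 5, 6]] + ["FT7", "FT8", "FT9", "FT10"]
    + [f"C{d}" for d in ["z", 1, 2, 3, 4, 5, 6]] + ["T7", "T8", "T9", "T10"]
    + [f"CP{d}" for d in ["z", 1, 2, 3, 4, 5, 6]] + ["TP7", "TP8", "TP9", "TP10"]
    + [f"P{d}" for d in ["z", 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]]
    + ["POz", "PO3", "PO4", "PO7", "PO8", "O1", "O2", "Oz", "Iz"]
)


def _build_1005(scalp_radius: float) -> Montage:
    R = scalp_radius
    labels: list[str] = []
    pts: list[np.ndarray] = []

    def add(label, point):
        labels.append(label)
        pts.append(point)

    def row_points(prefix, lat_prefix, s, max_slot):
        """One coronal row at sagittal fraction ``s`` (0=nasion, 1=inion)."""
        mid_polar = abs(0.5 - s) * 180.0
        mid_azim = 0.0 if s <= 0.5 else 180.0
        mid = _sph(R, mid_polar, mid_azim)
        add(f"{prefix}z", mid)
        ring_az = 180.0 * s
        for side, sgn, digits in (("L", -1.0, _SLOT_DIGIT_L), ("R", 1.0, _SLOT_DIGIT_R)):
            end = _sph(R, 72.0, sgn * ring_az)
            for slot in range(1, max_slot + 1):
                name_prefix = lat_prefix if slot >= 7 else prefix
                if slot <= 8:
                    p = _arc_point(mid, end, slot / 8.0)
                else:  # below the 10%-ring: 5% and 10% lower circles
                    p = _sph(R, 72.0 + 9.0 * (slot - 8), sgn * ring_az)
                add(f"{name_prefix}{digits[slot]}", p)

    # frontal pole / occipital rows live on the 10%-ring itself
    for prefix, s in (("Fp", 0.10), ("O", 0.90)):
        base_az = 180.0 * s
        add(f"{prefix}z", _sph(R, 72.0, 0.0 if s < 0.5 else 180.0))
        for sgn, digits in ((-1.0, _SLOT_DIGIT_L), (1.0, _SLOT_DIGIT_R)):
            for slot, step in ((1, 9.0), (2, 18.0)):
                az = step if s < 0.5 else 180.0 - step
                add(f"{prefix}{digits[slot]}", _sph(R, 72.0, sgn * az))

    for prefix, s in _FULL_ROWS:
        row_points(prefix, prefix, s, 10)
    for prefix, lat, s in _CENTRAL_ROWS:
        row_points(prefix, lat, s, 10)

    # occipito-inferior rows on the lower circles behind the head
    for prefix, polar in (("OI", 81.0), ("I", 90.0)):
        add(f"{prefix}z", _sph(R, polar, 180.0))
        for sgn, digits in ((-1.0, _SLOT_DIGIT_L), (1.0, _SLOT_DIGIT_R)):
            for slot, step in ((1, 9.0), (2, 18.0)):
                add(f"{prefix}{digits[slot]}", _sph(R, polar, sgn * (180.0 - step)))

    mont = Montage(tuple(labels), np.array(pts), system="10-05")
    # legacy temporal synonyms (old nomenclature), duplicate positions
    for legacy, modern in _LEGACY_SYNONYMS.items():
        labels.append(legacy)
        pts.append(mont.positions[mont.index_of(modern)])
    return Montage(tuple(labels), np.array(pts), system="10-05")


def build_montage(system: str = "10-05", scalp_radius: float = 0.100) -> Montage:
    """Electrode montage of the requested placement system on the scalp sphere.

    The 10-05 system yields 339 positions (the full 5% grid including the
    legacy temporal synonyms T3/T4/T5/T6, excluding ear/mastoid electrodes);
    the 10-10 system yields the classical 72-electrode chart, a label subset
    of the 10-05 set.  Cz is the vertex ``(0, 0, scalp_radius)``.
    """
    if system not in ("10-05", "10-10"):
        raise ConfigurationError(f"unknown montage system {system!r}")
    full = _build_1005(scalp_radius)
    if system == "10-05":
        return full
    return full.subset(TEN10_LABELS, system="10-10")


# ---------------------------------------------------------------------------
# Source space
# ---------------------------------------------------------------------------

def build_source_space(
    n_per_hemisphere: int = 4098,
    cortex_radius: float = 0.078,
    seed: int = 0,
    z_min: float = -0.02,
) -> SourceSpace:
    """Quasi-uniform bilateral source shell (Fibonacci lattice per hemisphere).

    Sources sit on the sphere of ``cortex_radius`` restricted to the upper cap
    ``z >= z_min`` (mimicking a cortical sheet with no sources at the skull
    base), mirror-symmetric about the midsagittal plane: ``n_per_hemisphere``
    sources with x < 0 (left) and their x-mirrored partners (right).
    Orientations are radial (surface-normal analogue of a fixed-orientation
    cortical model).  Deterministic for a fixed ``seed``, which sets the
    azimuthal phase of the lattice.
    """
    if n_per_hemisphere < 1:
        raise ConfigurationError("n_per_hemisphere must be >= 1")
    if not (-cortex_radius < z_min < cortex_radius):
        raise ConfigurationError("z_min must lie within the cortical shell")
    n = int(n_per_hemisphere)
    rng = np.random.default_rng(seed)
    phase = 0.05 + 0.9 * rng.random()  # keep azimuths strictly inside (0, pi)

    zfrac_min = z_min / cortex_radius
    i = np.arange(n)
    z = zfrac_min + (1.0 - zfrac_min) * (i + 0.5) / n  # area-uniform on the cap
    frac = np.mod(i * GOLDEN_FRAC + phase, 1.0)
    frac = 0.001 + 0.998 * frac  # open interval: no source exactly midsagittal
    azim = -np.pi * frac  # left hemisphere: x < 0
    rho = np.sqrt(1.0 - z**2)
    left = cortex_radius * np.column_stack(
        [rho * np.sin(azim), rho * np.cos(azim), z]
    )
    right = left * np.array([-1.0, 1.0, 1.0])
    positions = np.vstack([left, right])
    orientations = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    hemisphere = np.array(["L"] * n + ["R"] * n)
    return SourceSpace(positions, orientations, hemisphere, n)


# ---------------------------------------------------------------------------
# Forward solution: multilayer sphere Legendre series
# ---------------------------------------------------------------------------

def _layer_coefficients(shell: ShellModel) -> np.ndarray:
    """Scalp-surface radial profile S_n for a unit source harmonic.

    For each degree n the potential in shell j is
    ``V_j = (A_j r^n + B_j r^-(n+1)) Y_n``; the dipole's primary field
    contributes a known ``r^-(n+1)`` term in the innermost shell.  Continuity
    of potential and radial current at the two interfaces plus a vanishing
    normal current at the scalp give a 5x5 linear system per degree.  Radii
    are non-dimensionalized by the scalp radius for conditioning; the returned
    S_n is the scalp-surface value per unit source coefficient in those
    scaled units (the caller restores physical units).
    """
    r1, r2, R = (np.asarray(shell.radii) / shell.radii[2])
    s1, s2, s3 = shell.conductivities
    out = np.empty(shell.series_terms + 1)
    out[0] = 0.0
    for n in range(1, shell.series_terms + 1):
        a = np.zeros((5, 5))
        b = np.zeros(5)
        # unknowns: A1, A2, B2, A3, B3 ; source term c=1 at r^-(n+1) in shell 1
        a[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        b[0] = -(r1 ** -(n + 1))
        a[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        b[1] = s1 * (n + 1) * r1 ** -(n + 2)
        a[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        a[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        a[4] = [0, 0, 0, n * R ** (n - 1), -(n + 1) * R ** -(n + 2)]
        sol = np.linalg.solve(a, b)
        out[n] = sol[3] * R**n + sol[4] * R ** -(n + 1)
    return out


def forward_gain(
    shell: ShellModel,
    montage: Montage,
    src: SourceSpace,
    average_reference: bool = True,
) -> LeadField:
    """Lead field of unit dipoles in the three-shell sphere.

    Each column holds the scalp potentials (V per A.m) of one source's unit
    dipole, evaluated by the truncated Legendre expansion of the layered
    conductor; columns are average-referenced by default.  Supports arbitrary
    dipole orientations via the radial/tangential decomposition.
    """
    pos = src.positions
    radii = np.linalg.norm(pos, axis=1)
    if np.any(radii >= shell.radii[0]):
        raise DomainError("all sources must lie strictly inside the brain shell")

    R = shell.radii[2]
    sigma1 = shell.conductivities[0]
    S = _layer_coefficients(shell)  # scaled units (scalp radius = 1)

    e_hat = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    s_hat = pos / radii[:, None]
    u = np.clip(e_hat @ s_hat.T, -1.0, 1.0)  # (n_ch, n_src) cos(angle)

    m_r = np.einsum("ij,ij->i", src.orientations, s_hat)  # radial moment
    m_t = src.orientations - m_r[:, None] * s_hat  # tangential moment vector
    # (e_hat - u s_hat) . m_t, the tangential geometry factor
    t_geom = e_hat @ m_t.T - u * np.einsum("ij,ij->i", s_hat, m_t)[None, :]

    x = radii / R  # source radius in scalp units
    # series accumulation with stable recurrences:
    #   P_n   : Legendre polynomials
    #   Rn    : P_n^1 / sqrt(1-u^2)  (associated Legendre, sine factor removed)
    xn = x.copy()  # x^n
    p_prev = np.ones_like(u)
    p_cur = u.copy()
    r_prev = np.zeros_like(u)
    r_cur = np.ones_like(u)
    acc_rad = np.zeros_like(u)
    acc_tan = np.zeros_like(u)
    for n in range(1, shell.series_terms + 1):
        if n > 1:
            p_next = ((2 * n - 1) * u * p_cur - (n - 1) * p_prev) / n
            r_next = ((2 * n - 1) * u * r_cur - n * r_prev) / (n - 1)
            p_prev, p_cur = p_cur, p_next
            r_prev, r_cur = r_cur, r_next
        coef = S[n] * xn  # S_n * x^n
        acc_rad += (n * coef)[None, :] * p_cur
        acc_tan += coef[None, :] * r_cur
        xn *= x

    scale = 1.0 / (4.0 * np.pi * sigma1 * radii * R)
    gain = scale[None, :] * (m_r[None, :] * acc_rad + t_geom * acc_tan)

    if average_reference:
        gain = gain - gain.mean(axis=0, keepdims=True)

    col_norms = np.linalg.norm(gain, axis=0)
    if np.any(col_norms <= 0):
        bad = int(np.argmin(col_norms))
        raise DomainError(f"lead field column {bad} has zero norm")
    return LeadField(gain, montage, src, shell)


def homogeneous_sphere_potential(
    sigma: float, R: float, src_pos: np.ndarray, electrode: np.ndarray
) -> float:
    """Closed-form surface potential of a unit *radial* dipole in a single
    homogeneous sphere (independent oracle for the layered series).

    With x = b/R and D = sqrt(1 - 2 x u + x^2):
    ``V = [2 x (u - x)/D^3 + 1/D - 1] / (4 pi sigma b R)``.
    """
    b = float(np.linalg.norm(src_pos))
    u = float(np.dot(src_pos, electrode) / (b * np.linalg.norm(electrode)))
    x = b / R
    D = np.sqrt(1.0 - 2.0 * x * u + x * x)
    return (2.0 * x * (u - x) / D**3 + 1.0 / D - 1.0) / (4.0 * np.pi * sigma * b * R)
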