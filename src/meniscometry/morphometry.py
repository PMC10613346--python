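"""Index measurement on the axial footprint of a 3D label volume.

The three indices are computed on the top-down (axial) projection of each
structure, in anatomical mm coordinates:

* ``a`` — minimum ML width of the lateral-meniscus body (central third of
  its AP extent, peripheral-adjacent run per row),
* ``b`` — maximum ML width of the tibial plateau,
* ``e`` — maximum AP span over sagittal columns of the lateral footprint,
  with ``c``/``d`` the anterior/posterior horn runs on that column,
* ``L``/``M`` — AP extents of the lateral and medial footprints,

and the derived ratios ``rmt = a/b``, ``pcm = covered/e`` and
``lm_ratio = L/M``.

Length convention: a run of n occupied cells has length ``n * spacing``
(outer-edge to outer-edge of the voxel boxes). Ties in the max-diameter
column search break toward the peripheral side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyFootprintError, LabelAbsentError, NonAxisAlignedError
from .volume_io import LabelVolume

#: Fraction of the AP extent treated as the meniscal body (central region).
DEFAULT_BODY_FRACTION = 1.0 / 3.0


@dataclass
class Footprint2D:
    """Axial-plane binary footprint of one structure in mm coordinates.

    ``occupancy[ix, iy]`` is True where at least one voxel of the source
    label projects to the cell whose center is ``(x_coords[ix], y_coords[iy])``.
    """

    occupancy: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray
    source_label: int = 0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        if self.occupancy.shape != (self.x_coords.size, self.y_coords.size):
            raise ValueError("occupancy shape does not match coordinate arrays")
        for name, c in (("x", self.x_coords), ("y", self.y_coords)):
            if c.size > 1:
                d = np.diff(c)
                if not (d > 0).all():
                    raise ValueError(f"{name}_coords must be strictly increasing")
                if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                    raise ValueError(f"{name}_coords must be uniformly spaced")

    @property
    def dx(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0]) if self.x_coords.size > 1 else 1.0

    @property
    def dy(self) -> float:
        return float(self.y_coords[1] - self.y_coords[0]) if self.y_coords.size > 1 else 1.0

    @property
    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    def n_components(self) -> int:
        """Number of 8-connected components (flags torn/fragmented masks)."""
        from scipy import ndimage

        _, n = ndimage.label(self.occupancy, structure=np.ones((3, 3), dtype=int))
        return int(n)


@dataclass
class MorphometryResult:
    """Measured lengths (mm) and the three derived indices for one knee."""

    a_body_min_width_mm: float
    b_tibia_max_width_mm: float
    c_anterior_horn_mm: float
    d_posterior_horn_mm: float
    e_max_ap_diameter_mm: float
    L_lateral_ap_mm: float
    M_medial_ap_mm: float
    rmt: float
    pcm: float
    lm_ratio: float
    n_lateral_components: int = 1
    reliable: bool = True

    def __post_init__(self) -> None:
        lengths = (
            self.a_body_min_width_mm,
            self.b_tibia_max_width_mm,
            self.c_anterior_horn_mm,
            self.d_posterior_horn_mm,
            self.e_max_ap_diameter_mm,
            self.L_lateral_ap_mm,
            self.M_medial_ap_mm,
        )
        if any(v < 0 for v in lengths):
            raise ValueError("lengths must be non-negative")
        for name, v in (("b", self.b_tibia_max_width_mm), ("e", self.e_max_ap_diameter_mm), ("M", self.M_medial_ap_mm)):
            if v <= 0:
                raise ValueError(f"denominator length {name} must be > 0")
        if self.pcm > 1 + 1e-9:
            raise ValueError(f"pcm = {self.pcm} exceeds 1")


def project_axial(vol: LabelVolume, label: int) -> Footprint2D:
    """Collapse z: a cell is occupied iff >=1 voxel of ``label`` shares its (x, y).

    Requires the normalized affine to be axis-aligned (no in-plane rotation),
    which holds for every volume produced or re-read by this package.
    """
    rot = vol.affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise NonAxisAlignedError("affine has off-diagonal terms; cannot project on a regular grid")
    if np.any(np.diag(rot) <= 0):
        raise NonAxisAlignedError("affine axes not ascending; normalize orientation first")
    mask = vol.voxels == label
    if not mask.any():
        name = vol.label_map.get(label, "?")
        raise LabelAbsentError(f"label absent: id {label} ({name}) has no voxels")
    occupancy = mask.any(axis=2)
    nx, ny, _ = vol.voxels.shape
    x_coords = vol.affine[0, 0] * np.arange(nx) + vol.affine[0, 3]
    y_coords = vol.affine[1, 1] * np.arange(ny) + vol.affine[1, 3]
    return Footprint2D(occupancy=occupancy, x_coords=x_coords, y_coords=y_coords, source_label=label)


def _require_nonempty(fp: Footprint2D) -> None:
    if fp.is_empty:
        raise EmptyFootprintError("footprint is empty")


def _runs(mask_1d: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    padded = np.diff(np.r_[0, mask_1d.astype(np.int8), 0])
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def ap_extent(fp: Footprint2D) -> float:
    """AP (y) extent in mm: outer-edge span of the occupied rows."""
    _require_nonempty(fp)
    rows = np.flatnonzero(fp.occupancy.any(axis=0))
    return float((rows[-1] - rows[0] + 1) * fp.dy)


def ml_max_width(fp: Footprint2D) -> float:
    """Maximum over rows of the first-to-last occupied span along x, in mm."""
    _require_nonempty(fp)
    best = 0
    for iy in np.flatnonzero(fp.occupancy.any(axis=0)):
        xs = np.flatnonzero(fp.occupancy[:, iy])
        best = max(best, xs[-1] - xs[0] + 1)
    return float(best * fp.dx)


def body_min_width(
    fp: Footprint2D,
    side_sign: int = 1,
    body_fraction: float = DEFAULT_BODY_FRACTION,
) -> float:
    """Minimum body width ``a``: over rows in the central ``body_fraction`` of
    the AP extent, the length of the occupied run adjacent to the peripheral
    (``side_sign``) edge; return the minimum in mm.
    """
    _require_nonempty(fp)
    if side_sign not in (-1, 1):
        raise ValueError("side_sign must be +1 (peripheral at +x) or -1")
    rows = np.flatnonzero(fp.occupancy.any(axis=0))
    y_lo_edge = fp.y_coords[rows[0]] - fp.dy / 2
    span = (rows[-1] - rows[0] + 1) * fp.dy
    lo = y_lo_edge + span * (0.5 - body_fraction / 2)
    hi = y_lo_edge + span * (0.5 + body_fraction / 2)
    widths = []
    for iy in rows:
        y = fp.y_coords[iy]
        if not (lo <= y <= hi):
            continue
        runs = _runs(fp.occupancy[:, iy])
        if not runs:
            continue
        start, stop = runs[-1] if side_sign > 0 else runs[0]
        widths.append(stop - start)
    if not widths:
        raise EmptyFootprintError("no occupied rows in the central body region")
    return float(min(widths) * fp.dx)


def max_diameter_column(fp: Footprint2D, side_sign: int = 1) -> tuple[float, float]:
    """(x*, e): the ML coordinate whose column has the maximal first-to-last
    occupied span along y, and that span in mm.

    The maximal span is typically attained on a plateau of columns (the
    footprint's top is locally flat at grid resolution); we take the central
    column of that plateau, rounding toward the peripheral (``side_sign``)
    side, so a two-column tie returns the peripheral one. Taking an extreme
    plateau column instead would bias the horn runs by several voxels at
    coarse spacing.
    """
    _require_nonempty(fp)
    occ = fp.occupancy
    ny = occ.shape[1]
    first = np.argmax(occ, axis=1)
    last = ny - 1 - np.argmax(occ[:, ::-1], axis=1)
    any_col = occ.any(axis=1)
    spans = np.where(any_col, last - first + 1, 0)
    best = spans.max()
    candidates = np.flatnonzero(spans == best)
    k = len(candidates)
    ix = candidates[k // 2] if side_sign > 0 else candidates[(k - 1) // 2]
    return float(fp.x_coords[ix]), float(best * fp.dy)


def horn_coverage(fp: Footprint2D, x_star: float) -> tuple[float, float, float]:
    """Horn runs on the column nearest ``x_star``.

    Returns ``(c, d, covered)`` in mm: ``c`` the anterior-most (largest-y)
    run, ``d`` the posterior-most run, ``covered`` the total occupied length
    of the column (middle runs included). A single full-span run yields
    ``c = d = covered / 2`` so that ``c + d`` equals the covered length.
    """
    ix = int(np.argmin(np.abs(fp.x_coords - x_star)))
    column = fp.occupancy[ix]
    runs = _runs(column)
    if not runs:
        raise EmptyFootprintError(f"column at x = {x_star} mm is empty")
    covered = float(sum(stop - start for start, stop in runs) * fp.dy)
    if len(runs) == 1:
        c = d = covered / 2
    else:
        d = float((runs[0][1] - runs[0][0]) * fp.dy)  # posterior-most (lowest y)
        c = float((runs[-1][1] - runs[-1][0]) * fp.dy)  # anterior-most
    return c, d, covered


def indices_from_lengths(
    a: float, b: float, c: float, d: float, e: float, L: float, M: float
) -> MorphometryResult:
    """Build a result directly from the seven lengths (mm) via the three ratios."""
    return MorphometryResult(
        a_body_min_width_mm=a,
        b_tibia_max_width_mm=b,
        c_anterior_horn_mm=c,
        d_posterior_horn_mm=d,
        e_max_ap_diameter_mm=e,
        L_lateral_ap_mm=L,
        M_medial_ap_mm=M,
        rmt=a / b,
        pcm=(c + d) / e,
        lm_ratio=L / M,
    )


def lm_ratio_from_lengths(L_mm: float, M_mm: float) -> float:
    """L/M ratio from the two AP diameters (mm)."""
    if M_mm <= 0:
        raise ValueError("M must be > 0")
    return L_mm / M_mm


def compute_indices(
    vol: LabelVolume,
    body_fraction: float = DEFAULT_BODY_FRACTION,
    meniscus: str = "lateral",
) -> MorphometryResult:
    """Measure all lengths and indices on one labelled knee volume.

    ``meniscus`` selects which meniscus plays the "disease side" role for
    a, c, d, e (default lateral, the clinically relevant side); L and M are
    always the lateral and medial AP extents.
    """
    if meniscus not in ("lateral", "medial"):
        raise ValueError("meniscus must be 'lateral' or 'medial'")
    lat = vol.label_id("lateral_meniscus")
    med = vol.label_id("medial_meniscus")
    tib = vol.label_id("tibial_plateau")
    fp_lat = project_axial(vol, lat)
    fp_med = project_axial(vol, med)
    fp_tib = project_axial(vol, tib)

    target, sign = (fp_lat, 1) if meniscus == "lateral" else (fp_med, -1)
    a = body_min_width(target, side_sign=sign, body_fraction=body_fraction)
    b = ml_max_width(fp_tib)
    x_star, e = max_diameter_column(target, side_sign=sign)
    c, d, covered = horn_coverage(target, x_star)
    L = ap_extent(fp_lat)
    M = ap_extent(fp_med)
    n_comp = target.n_components()
    return MorphometryResult(
        a_body_min_width_mm=a,
        b_tibia_max_width_mm=b,
        c_anterior_horn_mm=c,
        d_posterior_horn_mm=d,
        e_max_ap_diameter_mm=e,
        L_lateral_ap_mm=L,
        M_medial_ap_mm=M,
        rmt=a / b,
        pcm=covered / e,
        lm_ratio=L / M,
        n_lateral_components=n_comp,
        reliable=n_comp == 1,
    )
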