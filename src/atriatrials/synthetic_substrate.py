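"""Synthetic 2-D atrial substrates with low-voltage-area (LVA) patterns.

Stands in for patient bipolar-voltage maps: a rectangular sheet is split into
a left-atrial (LA) zone — parcellated into 13 segments, with segments 1-4
forming the posterior-wall stripe — and a structurally-healthy right-atrial
proxy zone.  LVA patterns of controlled extent and patchiness are produced by
thresholding a Gaussian-smoothed random field at the quantile that realizes
the requested LVA fraction; bipolar voltage below 0.5 mV defines LVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError

LVA_THRESHOLD_MV = 0.5
RA_PROXY_LABEL = 14
LA_LABELS = tuple(range(1, 14))
POSTERIOR_LABELS = (1, 2, 3, 4)
LA_COLUMN_FRACTION = 0.6   # left 60% of columns form the LA zone
RA_BI_MV = 1.5             # healthy bipolar voltage assigned to the RA proxy


@dataclass
class SubstrateSheet:
    """Node-centred rectangular sheet; arrays are (ny, nx), row-major."""

    nx: int
    ny: int
    dx: float                       # node spacing, mm
    labels: np.ndarray              # int8 region labels, 1-13 LA, 14 RA proxy
    fiber_angle: np.ndarray         # radians
    bi: Optional[np.ndarray] = None     # bipolar voltage, mV
    lva: Optional[np.ndarray] = None    # bool mask, Bi < 0.5 mV
    pattern: Optional["LVAPattern"] = None

    @property
    def shape(self):
        return (self.ny, self.nx)

    @property
    def n_nodes(self):
        return self.nx * self.ny

    def la_mask(self) -> np.ndarray:
        return self.labels <= 13

    def ra_mask(self) -> np.ndarray:
        return self.labels == RA_PROXY_LABEL

    def lva_mask(self) -> np.ndarray:
        if self.lva is None:
            raise ValidationError("no LVA pattern generated for this sheet")
        return self.lva


@dataclass
class LVAPattern:
    """Target extent/patchiness of an LVA distribution."""

    la_fraction: float                      # target LA LVA fraction, 0-1
    posterior_fraction: Optional[float] = None  # target fraction in segments 1-4
    patch_scale_mm: float = 6.0             # Gaussian smoothing length
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.la_fraction <= 1.0):
            raise ValidationError(f"la_fraction outside [0,1]: {self.la_fraction}")
        if self.posterior_fraction is not None and not (
                0.0 <= self.posterior_fraction <= 1.0):
            raise ValidationError(
                f"posterior_fraction outside [0,1]: {self.posterior_fraction}")
        if self.patch_scale_mm <= 0:
            raise ValidationError("patch_scale_mm must be > 0")


def _parcellate(nx: int, ny: int) -> np.ndarray:
    """Fixed rectangular 13-segment tiling of the LA zone plus RA proxy.

    Row bands of the LA zone, top to bottom: posterior stripe (1-4),
    inferior+septal (5, 6, 7), anterior (8-11), lateral+appendage (12, 13).
    """
    labels = np.full((ny, nx), RA_PROXY_LABEL, dtype=np.int8)
    nla = int(round(LA_COLUMN_FRACTION * nx))
    bands = np.array_split(np.arange(ny), 4)
    band_labels = [(1, 2, 3, 4), (5, 6, 7), (8, 9, 10, 11), (12, 13)]
    for rows, labs in zip(bands, band_labels):
        cols = np.array_split(np.arange(nla), len(labs))
        for c, lab in zip(cols, labs):
            if len(rows) == 0 or len(c) == 0:
                raise ValidationError(
                    f"grid {nx}x{ny} too small to host the 14-region parcellation")
            labels[np.ix_(rows, c)] = lab
    return labels


def build_sheet(dims=(240, 200), dx: float = 0.3, fiber_spec=None) -> SubstrateSheet:
    """Construct a parcellated sheet with a smooth fiber-angle field.

    ``dims`` is (nx, ny); ``dx`` in mm (0.2-0.5).  ``fiber_spec`` is a dict:
    ``{"kind": "uniform", "angle": a}`` or ``{"kind": "wave", "amplitude": a,
    "wavelength_mm": w}`` (default: a gentle 0.35 rad wave, giving fibers
    roughly along x with a smooth spatial rotation).  Deterministic.
    """
    nx, ny = dims
    if nx < 50 or ny < 50:
        raise ValidationError(f"dims must be >= 50x50, got {dims}")
    if not (0.2 <= dx <= 0.5):
        raise ValidationError(f"dx must be in [0.2, 0.5] mm, got {dx}")
    labels = _parcellate(nx, ny)
    if fiber_spec is None:
        fiber_spec = {"kind": "wave", "amplitude": 0.35, "wavelength_mm": 40.0}
    yy, xx = np.meshgrid(np.arange(ny) * dx, np.arange(nx) * dx, indexing="ij")
    if fiber_spec["kind"] == "uniform":
        angle = np.full((ny, nx), float(fiber_spec.get("angle", 0.0)))
    elif fiber_spec["kind"] == "wave":
        a = float(fiber_spec["amplitude"])
        w = float(fiber_spec["wavelength_mm"])
        angle = a * np.sin(2 * np.pi * xx / w) * np.cos(2 * np.pi * yy / w)
    else:
        raise ValidationError(f"unknown fiber_spec kind {fiber_spec['kind']!r}")
    return SubstrateSheet(nx=nx, ny=ny, dx=dx, labels=labels,
                          fiber_angle=angle.astype(np.float64))


def _threshold_region(z, region, target):
    """LVA submask of ``region`` hitting ``target`` fraction via a quantile cut."""
    mask = np.zeros_like(region, dtype=bool)
    if target <= 0.0:
        return mask, np.inf
    vals = z[region]
    thr = float(np.quantile(vals, 1.0 - target))
    mask[region] = z[region] > thr
    return mask, thr


def generate_voltage_map(sheet: SubstrateSheet, pattern: LVAPattern) -> SubstrateSheet:
    """Fill the bipolar-voltage field to realize an LVA pattern (in place).

    A white-noise field is smoothed with a Gaussian kernel of width
    ``patch_scale_mm`` and thresholded at the quantile matching the target LA
    fraction (posterior and non-posterior LA thresholded separately when a
    posterior target is given).  Non-LVA nodes receive Bi >= 0.5 mV and the
    RA proxy is always healthy.  Reproducible under ``pattern.seed``.
    """
    rng = np.random.default_rng(pattern.seed)
    z = rng.standard_normal(sheet.shape)
    z = ndimage.gaussian_filter(z, sigma=pattern.patch_scale_mm / sheet.dx,
                                mode="reflect")
    sd = z.std() or 1.0
    z /= sd

    la = sheet.la_mask()
    post = np.isin(sheet.labels, POSTERIOR_LABELS)
    rest = la & ~post

    if pattern.posterior_fraction is None:
        lva, _ = _threshold_region(z, la, pattern.la_fraction)
    else:
        n_la, n_post = la.sum(), post.sum()
        rest_target = (pattern.la_fraction * n_la
                       - pattern.posterior_fraction * n_post) / (n_la - n_post)
        if not (0.0 <= rest_target <= 1.0):
            raise ValidationError(
                "unattainable combination: posterior fraction "
                f"{pattern.posterior_fraction} incompatible with LA fraction "
                f"{pattern.la_fraction}")
        m_post, _ = _threshold_region(z, post, pattern.posterior_fraction)
        m_rest, _ = _threshold_region(z, rest, rest_target)
        lva = m_post | m_rest

    # map the field to voltages: LVA strictly below 0.5 mV, the rest above
    bi = np.empty(sheet.shape)
    scale = 0.45
    depth = np.clip(z - np.quantile(z, 0.5), -3.0, 3.0)
    bi[:] = np.clip(LVA_THRESHOLD_MV + scale * np.abs(depth) + 0.02, 0.5, 3.0)
    bi[lva] = np.clip(LVA_THRESHOLD_MV - scale * (np.abs(depth[lva]) + 0.05),
                      0.02, 0.49)
    bi[sheet.ra_mask()] = RA_BI_MV
    sheet.bi = bi
    sheet.lva = binarize(sheet)
    sheet.pattern = pattern
    return sheet


def binarize(sheet: SubstrateSheet, threshold: float = LVA_THRESHOLD_MV) -> np.ndarray:
    """LVA mask: nodes with Bi strictly below ``threshold``; RA proxy forced healthy."""
    if sheet.bi is None:
        raise ValidationError("sheet has no bipolar-voltage field")
    mask = sheet.bi < threshold
    mask[sheet.ra_mask()] = False
    return mask


def lva_fraction(sheet: SubstrateSheet, region_selector="la") -> float:
    """LVA nodes / total nodes within a region ('la' or an iterable of labels)."""
    mask = sheet.lva_mask()
    if isinstance(region_selector, str):
        if region_selector != "la":
            raise ValidationError(f"unknown selector {region_selector!r}")
        sel = sheet.la_mask()
    else:
        labs = list(region_selector)
        if not labs:
            raise ValidationError("empty region selector")
        sel = np.isin(sheet.labels, labs)
    if not sel.any():
        raise ValidationError("selector matches no nodes")
    return float(mask[sel].sum() / sel.sum())


def patch_areas(sheet: SubstrateSheet) -> np.ndarray:
    """Areas (mm^2) of 8-connected LVA patches."""
    structure = np.ones((3, 3), dtype=int)
    lab, n = ndimage.label(sheet.lva_mask(), structure=structure)
    if n == 0:
        return np.array([])
    counts = np.bincount(lab.ravel())[1:]
    return counts * sheet.dx ** 2


def segment_fractions(sheet: SubstrateSheet) -> pd.DataFrame:
    """Per-segment LVA fractions (CSV-exportable report)."""
    rows = [{"segment": lab, "lva_fraction": lva_fraction(sheet, [lab])}
            for lab in LA_LABELS]
    rows.append({"segment": "posterior(1-4)",
                 "lva_fraction": lva_fraction(sheet, POSTERIOR_LABELS)})
    rows.append({"segment": "LA", "lva_fraction": lva_fraction(sheet, "la")})
    return pd.DataFrame(rows)


def save_sheet(sheet: SubstrateSheet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dx"] = sheet.dx
        f.create_dataset("labels", data=sheet.labels)
        f.create_dataset("fiber_angle", data=sheet.fiber_angle)
        if sheet.bi is not None:
            f.create_dataset("bi", data=sheet.bi)
        if sheet.lva is not None:
            f.create_dataset("lva", data=sheet.lva)


def load_sheet(path) -> SubstrateSheet:
    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        ny, nx = labels.shape
        sheet = SubstrateSheet(nx=nx, ny=ny, dx=float(f.attrs["dx"]),
                               labels=labels, fiber_angle=f["fiber_angle"][()])
        if "bi" in f:
            sheet.bi = f["bi"][()]
        if "lva" in f:
            sheet.lva = f["lva"][()]
    return sheet


def import_bi_csv(sheet: SubstrateSheet, path) -> SubstrateSheet:
    """Load user per-node bipolar voltages: CSV columns (node, bi_mv).

    ``node`` is the 0-based row-major node index.  Nodes not listed keep the
    healthy default; the RA proxy stays non-LVA regardless of input.
    """
    df = pd.read_csv(path)
    bi = np.full(sheet.shape, RA_BI_MV).ravel()
    idx = df["node"].to_numpy(int)
    if idx.min() < 0 or idx.max() >= sheet.n_nodes:
        raise ValidationError("node index outside the sheet")
    bi[idx] = df["bi_mv"].to_numpy(float)
    sheet.bi = bi.reshape(sheet.shape)
    sheet.lva = binarize(sheet)
    sheet.pattern = None
    return sheet
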