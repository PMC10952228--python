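"""Per-node dominant-frequency (DF) maps and high-frequency density maps.

For a sustained AF episode every node's activation rate defines a DF map.
Each map is discretized into three categories — low (<= 10th percentile),
middle, and high (>= 90th percentile) — computed per episode over valid
nodes, so maps from episodes with different absolute frequency ranges remain
comparable.  Superimposing the high-frequency category across episodes of
one substrate yields a density map of preferential fast-driver regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

MIN_ACTIVATIONS = 4     # activations required for a node's DF to be valid

CAT_INVALID, CAT_LOW, CAT_MID, CAT_HIGH = -1, 0, 1, 2


@dataclass
class DFMap:
    df: np.ndarray          # (ny, nx) Hz; nan on invalid nodes
    valid: np.ndarray       # (ny, nx) bool
    episode_id: str = ""


@dataclass
class DiscreteFMap:
    category: np.ndarray    # (ny, nx) int8: -1 invalid, 0 low, 1 mid, 2 high
    p10: float              # Hz
    p90: float              # Hz
    episode_id: str = ""


def node_df_map(result, min_activations: int = MIN_ACTIVATIONS,
                window: Optional[tuple] = None) -> DFMap:
    """DF per node from its activation series (inverse mean cycle length).

    Refuses non-sustained episodes: DF maps are only defined where
    fibrillatory activity persisted.  ``window`` optionally restricts to
    activations inside (t0, t1) ms.
    """
    if not result.sustained:
        raise ValidationError("DF maps are computed for sustained episodes only")
    ny, nx = result.shape
    counts = result.act_counts.reshape(ny, nx)
    df = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), bool)
    times = result.act_times.reshape(ny, nx, -1)
    for j in range(ny):
        for i in range(nx):
            c = counts[j, i]
            t = times[j, i, :c].astype(float)
            if window is not None:
                t = t[(t >= window[0]) & (t <= window[1])]
            if len(t) < min_activations:
                continue
            mean_cl = np.diff(t).mean()
            if mean_cl > 0:
                df[j, i] = 1000.0 / mean_cl
                valid[j, i] = True
    return DFMap(df=df, valid=valid, episode_id=result.profile_id)


def discretize(dfmap: DFMap) -> DiscreteFMap:
    """Three-level discretization at the episode's own 10th/90th percentiles.

    Inclusive boundary rule: low iff DF <= p10, high iff DF >= p90.  A
    degenerate all-equal map (p10 == p90) is classified entirely as middle.
    """
    vals = dfmap.df[dfmap.valid]
    if vals.size < 10:
        raise ValidationError(f"need >= 10 valid nodes, got {vals.size}")
    p10, p90 = np.percentile(vals, [10.0, 90.0])
    cat = np.full(dfmap.df.shape, CAT_INVALID, dtype=np.int8)
    cat[dfmap.valid] = CAT_MID
    if p90 > p10:
        cat[dfmap.valid & (dfmap.df <= p10)] = CAT_LOW
        cat[dfmap.valid & (dfmap.df >= p90)] = CAT_HIGH
    return DiscreteFMap(category=cat, p10=float(p10), p90=float(p90),
                        episode_id=dfmap.episode_id)


def density_map(discrete_maps: Sequence[DiscreteFMap],
                normalize: bool = False) -> np.ndarray:
    """Per-node count (or fraction) of episodes in which the node was
    high-frequency.  All maps must share the grid geometry."""
    if not discrete_maps:
        raise ValidationError("no discrete maps given")
    shape = discrete_maps[0].category.shape
    out = np.zeros(shape, dtype=float)
    for m in discrete_maps:
        if m.category.shape != shape:
            raise ValidationError("discrete maps have mismatched geometry")
        out += (m.category == CAT_HIGH)
    if normalize:
        out /= len(discrete_maps)
    return out


def df_map_to_csv(dfmap: DFMap, path) -> None:
    """Row-major per-node export: node index, DF (Hz), validity flag."""
    import pandas as pd
    pd.DataFrame({"node": np.arange(dfmap.df.size),
                  "df_hz": dfmap.df.ravel(),
                  "valid": dfmap.valid.ravel()}).to_csv(path, index=False)


def render_map_png(array2d, path, cmap: str = "viridis", title=None) -> None:
    """Render a per-node map (DF, category or density) to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(array2d, origin="lower", cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.85)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x node")
    ax.set_ylabel("y node")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def category_fractions(dmap: DiscreteFMap) -> dict:
    """Fractions of valid nodes per category (sums to 1)."""
    valid = dmap.category != CAT_INVALID
    n = valid.sum()
    if n == 0:
        raise ValidationError("map has no valid nodes")
    return {"low": float((dmap.category == CAT_LOW).sum() / n),
            "mid": float((dmap.category == CAT_MID).sum() / n),
            "high": float((dmap.category == CAT_HIGH).sum() / n)}
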