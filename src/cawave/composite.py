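"""Composite training images: nine same-group waveforms tiled 3×3.

A composite is a single training example built from nine *distinct*
randomly drawn waveform images of one group.  Reuse of a waveform
across different composites is permitted (and is what lets a pool of N
waveforms yield N composites); duplication within one composite is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DimensionError, InsufficientPoolError, LabelError, ParameterError
from .render import WaveformImage

__all__ = ["CompositeImage", "build_composites", "tile_3x3", "composite_manifest", "TILES_PER_COMPOSITE"]

#: tile count of one composite (3 × 3 grid)
TILES_PER_COMPOSITE = 9
_GRID = 3


@dataclass
class CompositeImage:
    """A 3×3 grid of nine member waveform images with one group label."""

    pixels: np.ndarray  # uint8, (3*h, 3*w)
    member_ids: tuple[str, ...]
    group: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.member_ids) != TILES_PER_COMPOSITE:
            raise ParameterError("member_ids: a composite has exactly 9 members")
        if len(set(self.member_ids)) != TILES_PER_COMPOSITE:
            raise ParameterError("member_ids: members must be distinct")

    # keep attribute parity with WaveformImage for the learning stage
    @property
    def roi_id(self) -> str:
        return "+".join(self.member_ids)

    @property
    def substance(self) -> None:
        return None


def tile_3x3(
    tiles: Sequence[np.ndarray], order_seed: int | None = None
) -> np.ndarray:
    """Place nine equal-size tiles row-major onto a 3×3 raster.

    ``order_seed=None`` keeps the input order; an integer seed applies a
    reproducible random permutation of the nine tiles first.
    """
    if len(tiles) != TILES_PER_COMPOSITE:
        raise ParameterError(f"tiles: expected {TILES_PER_COMPOSITE}, got {len(tiles)}")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise DimensionError(f"tiles: heterogeneous sizes {sorted(shapes)}")
    h, w = tiles[0].shape
    order = (
        np.arange(TILES_PER_COMPOSITE)
        if order_seed is None
        else np.random.default_rng(order_seed).permutation(TILES_PER_COMPOSITE)
    )
    out = np.empty((_GRID * h, _GRID * w), dtype=tiles[0].dtype)
    for slot, src in enumerate(order):
        r, c = divmod(slot, _GRID)
        out[r * h : (r + 1) * h, c * w : (c + 1) * w] = tiles[src]
    return out


def build_composites(
    pool: Sequence[WaveformImage],
    group: str,
    n_out: int,
    seed: int,
    reuse_across: bool = True,
) -> list[CompositeImage]:
    """Draw ``n_out`` composites from a single-group waveform pool.

    Each composite samples nine distinct members uniformly without
    replacement.  With ``reuse_across=True`` (default) a waveform may
    appear in several composites; with ``False`` every waveform is used
    at most once overall, requiring ``9 × n_out`` pool images.
    Deterministic given (pool order, n_out, seed).
    """
    if n_out < 1:
        raise ParameterError("n_out: must be >= 1")
    bad = [im.group for im in pool if im.group != group]
    if bad:
        raise LabelError(f"pool contains groups other than {group!r}: {sorted(set(bad))}")
    if len(pool) < TILES_PER_COMPOSITE:
        raise InsufficientPoolError(
            f"pool of {len(pool)} images; need at least {TILES_PER_COMPOSITE}"
        )
    ids = [im.roi_id for im in pool]
    if len(set(ids)) != len(ids):
        raise ParameterError("pool: duplicate roi_ids; member identity must be unique")

    rng = np.random.default_rng(seed)
    if not reuse_across:
        if n_out * TILES_PER_COMPOSITE > len(pool):
            raise InsufficientPoolError(
                f"reuse_across=False needs {n_out * TILES_PER_COMPOSITE} distinct "
                f"waveforms, pool has {len(pool)}"
            )
        shuffled = rng.permutation(len(pool))
        draws = [
            shuffled[i * TILES_PER_COMPOSITE : (i + 1) * TILES_PER_COMPOSITE]
            for i in range(n_out)
        ]
    else:
        draws = [
            rng.choice(len(pool), size=TILES_PER_COMPOSITE, replace=False)
            for _ in range(n_out)
        ]

    out = []
    for members in draws:
        order_seed = int(rng.integers(0, 2**31))
        raster = tile_3x3([pool[i].pixels for i in members], order_seed=order_seed)
        out.append(
            CompositeImage(
                pixels=raster,
                member_ids=tuple(ids[i] for i in members),
                group=group,
                seed=order_seed,
            )
        )
    return out


def composite_manifest(
    composites: Sequence[CompositeImage], filenames: Sequence[str], path
) -> pd.DataFrame:
    if len(composites) != len(filenames):
        raise ParameterError("filenames: must align one-to-one with composites")
    df = pd.DataFrame(
        {
            "filename": list(filenames),
            "member_ids": ["|".join(c.member_ids) for c in composites],
            "group": [c.group for c in composites],
            "seed": [c.seed for c in composites],
        }
    )
    df.to_csv(path, index=False)
    return df
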