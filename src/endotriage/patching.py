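"""Regular-grid patch extraction and labelling.

Patches are taken at level 0 on a grid anchored at the slide origin, with
the stride equal to the patch size by default.  Each patch's footprint in
the level-5 region mask (``size/32`` cells per side) decides whether it is
processed: either any tissue cell admits it, or tissue must be the most
common class among tissue / blood-mucus / background (ties favour tissue).
A patch containing any malignant cell is labelled malignant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import RegionClass
from .pyramid import ImagePyramid, read_region

logger = logging.getLogger(__name__)

TISSUE_RULES = ("any_tissue", "majority_tissue")


@dataclass
class PatchRecord:
    slide_id: str
    x: int  # level-0 top-left, pixels
    y: int
    size: int
    tissue_fraction: float
    blood_fraction: float
    background_fraction: float
    label: str | None = None

    @property
    def footprint(self) -> tuple[int, int, int]:
        """(row, col, side) of the level-5 cell block covered by the patch."""
        return (self.y // 32, self.x // 32, self.size // 32)


def _fractions(block: np.ndarray) -> tuple[float, float, float]:
    n = block.size
    tissue = int(((block == RegionClass.OTHER_BENIGN) |
                  (block == RegionClass.MALIGNANT)).sum())
    blood = int((block == RegionClass.BLOOD_MUCUS).sum())
    background = n - tissue - blood
    return tissue / n, blood / n, background / n


def grid_patches(
    mask: np.ndarray,
    patch_size: int = 256,
    stride: int | None = None,
    rule: str = "any_tissue",
    slide_id: str = "",
    min_patches: int = 0,
    seed: int = 0,
) -> list[PatchRecord]:
    """Emit patch records over a regular grid anchored at (0, 0).

    Partial edge patches (whose footprint would exceed the mask) are
    discarded.  ``rule`` is ``any_tissue`` (at least one tissue cell in the
    footprint) or ``majority_tissue`` (tissue is the most common of tissue,
    blood/mucus and background; ties broken in favour of tissue).

    Fragmented slides can lose most of their tissue to grid misalignment
    under the majority rule.  As an optional remedy (off by default), when
    fewer than ``min_patches`` records are admitted, additional patches are
    placed at random tissue-containing positions until the minimum is met.
    """
    if patch_size <= 0 or patch_size % 32 != 0:
        raise ValueError("patch_size must be a positive multiple of 32")
    stride = patch_size if stride is None else stride
    if stride <= 0:
        raise ValueError("stride must be positive")
    if rule not in TISSUE_RULES:
        raise ValueError(f"unknown tissue rule {rule!r}")
    side = patch_size // 32
    h5, w5 = mask.shape
    records = []
    for y in range(0, (h5 - side) * 32 + 1, stride):
        for x in range(0, (w5 - side) * 32 + 1, stride):
            fy, fx = y // 32, x // 32
            if fy + side > h5 or fx + side > w5:
                continue
            block = mask[fy : fy + side, fx : fx + side]
            n = block.size
            tissue_cells = int(((block == RegionClass.OTHER_BENIGN) |
                                (block == RegionClass.MALIGNANT)).sum())
            blood_cells = int((block == RegionClass.BLOOD_MUCUS).sum())
            background_cells = n - tissue_cells - blood_cells
            tf, bf, gf = tissue_cells / n, blood_cells / n, background_cells / n
            if rule == "any_tissue":
                admit = tissue_cells >= 1
            else:
                admit = (
                    tissue_cells >= 1
                    and tissue_cells >= blood_cells
                    and tissue_cells >= background_cells
                )
            if admit:
                records.append(
                    PatchRecord(slide_id, x, y, patch_size, tf, bf, gf)
                )
    if min_patches > 0 and len(records) < min_patches:
        records += _random_tissue_patches(
            mask, patch_size, min_patches - len(records),
            {(r.x, r.y) for r in records}, slide_id, seed,
        )
    return records


def _random_tissue_patches(
    mask: np.ndarray,
    patch_size: int,
    n_needed: int,
    taken: set[tuple[int, int]],
    slide_id: str,
    seed: int,
) -> list[PatchRecord]:
    """Randomly place patches whose footprint touches tissue (cell-aligned)."""
    side = patch_size // 32
    h5, w5 = mask.shape
    tissue = (mask == RegionClass.OTHER_BENIGN) | (mask == RegionClass.MALIGNANT)
    rng = np.random.default_rng(seed)
    out: list[PatchRecord] = []
    for _ in range(200 * max(n_needed, 1)):
        if len(out) >= n_needed:
            break
        fy = int(rng.integers(0, max(h5 - side, 0) + 1))
        fx = int(rng.integers(0, max(w5 - side, 0) + 1))
        x, y = fx * 32, fy * 32
        if (x, y) in taken:
            continue
        block = mask[fy : fy + side, fx : fx + side]
        if not tissue[fy : fy + side, fx : fx + side].any():
            continue
        n = block.size
        t = int(tissue[fy : fy + side, fx : fx + side].sum())
        b = int((block == RegionClass.BLOOD_MUCUS).sum())
        taken.add((x, y))
        out.append(
            PatchRecord(slide_id, x, y, patch_size, t / n, b / n,
                        (n - t - b) / n)
        )
    return out


def label_patch(record: PatchRecord, mask: np.ndarray) -> str:
    """Malignant iff the footprint contains any malignant cell."""
    fy, fx, side = record.footprint
    h5, w5 = mask.shape
    if fy < 0 or fx < 0 or fy + side > h5 or fx + side > w5:
        raise ValueError("patch footprint out of mask bounds")
    block = mask[fy : fy + side, fx : fx + side]
    return "malignant" if (block == RegionClass.MALIGNANT).any() else "other_or_benign"


def label_patches(records: list[PatchRecord], mask: np.ndarray) -> list[PatchRecord]:
    for rec in records:
        rec.label = label_patch(rec, mask)
    return records


def sample_balanced(
    records: list[PatchRecord], n_per_class: int, seed: int = 0
) -> list[PatchRecord]:
    """Seeded, order-stable balanced sample of labelled records.

    Exactly ``n_per_class`` records per label, or every available record of
    a class (with a logged warning) when fewer exist.
    """
    by_label: dict[str, list[PatchRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise ValueError("records must be labelled before sampling")
        by_label.setdefault(rec.label, []).append(rec)
    if len(by_label) < 2:
        raise ValueError("both patch labels must be present")
    rng = np.random.default_rng(seed)
    out: list[PatchRecord] = []
    for label in sorted(by_label):
        pool = by_label[label]
        if len(pool) < n_per_class:
            logger.warning(
                "only %d %r patches available (requested %d); using all",
                len(pool), label, n_per_class,
            )
            chosen = list(pool)
        else:
            idx = rng.choice(len(pool), size=n_per_class, replace=False)
            chosen = [pool[i] for i in sorted(idx)]
        out.extend(chosen)
    return out


def extract_patch_image(pyramid: ImagePyramid, record: PatchRecord) -> np.ndarray:
    """The ``size x size`` level-0 raster under a record."""
    return read_region(pyramid, 0, record.x, record.y, record.size, record.size)


def records_to_frame(records: list[PatchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "x": r.x,
                "y": r.y,
                "size": r.size,
                "tissue_fraction": r.tissue_fraction,
                "blood_fraction": r.blood_fraction,
                "background_fraction": r.background_fraction,
                "label": r.label if r.label is not None else "",
            }
            for r in records
        ]
    )


def records_from_frame(frame: pd.DataFrame) -> list[PatchRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            PatchRecord(
                slide_id=str(row.slide_id),
                x=int(row.x),
                y=int(row.y),
                size=int(row.size),
                tissue_fraction=float(row.tissue_fraction),
                blood_fraction=float(row.blood_fraction),
                background_fraction=float(row.background_fraction),
                label=str(row.label) or None,
            )
        )
    return records
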