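"""Seeded synthetic image datasets with a two-level hierarchical label structure.

The generator emulates the structure of a clinical screening dataset without
any clinical content: each **level-1** class fixes a coarse, image-wide visual
attribute (a background hue band plus a large centred motif shape) and each
**level-2** subclass fixes a fine attribute — a striped "lesion" patch of
class-specific orientation and spatial frequency drawn inside an axis-aligned
box placed uniformly at random.  The box position is recorded per record, so
saliency maps can be scored against a known ground-truth region.

Class imbalance (default largest:smallest = 10:1 across level-2 classes) and
optional multi-label composites (two subclasses superimposed in one image,
labels upward-closed across levels) mirror the properties the hierarchical
classifier is designed to cope with.  Everything is deterministic given the
seed.  Images are modelled in [0, 1] internally and stored as 8-bit RGB PNG.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .taxonomy import (
    DiseaseTaxonomy,
    MultiLevelLabel,
    bundled_taxonomy,
    expand_labels,
)

__all__ = [
    "SynthConfig",
    "SynthRecord",
    "SyntheticDataset",
    "default_counts",
    "desk_config",
    "generate_arrays",
    "generate_dataset",
    "load_manifest",
    "save_manifest",
    "load_images",
    "train_test_partition",
    "labels_to_matrices",
]

MANIFEST_COLUMNS = ["image_path", "level2_labels", "lesion_boxes"]


@dataclass
class SynthConfig:
    """Generation parameters for one synthetic dataset."""

    taxonomy: DiseaseTaxonomy
    image_size: int = 96
    n_per_class: dict[str, int] = field(default_factory=dict)
    composite_fraction: float = 0.1
    noise_sd: float = 0.02
    lesion_fraction: float = 1 / 3  # lesion box side as a fraction of image side
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.composite_fraction <= 1.0:
            raise ValueError("composite_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        order2 = self.taxonomy.class_order[2]
        if not self.n_per_class:
            self.n_per_class = default_counts(self.taxonomy)
        for cid, n in self.n_per_class.items():
            if cid not in order2:
                raise ValueError(f"n_per_class references unknown level-2 class {cid!r}")
            if n < 0:
                raise ValueError("image counts must be >= 0")


@dataclass
class SynthRecord:
    """Ground truth for one generated image."""

    image_path: str
    label: MultiLevelLabel
    level2_ids: list[str]
    lesion_boxes: dict[str, tuple[int, int, int, int]]  # (x0, y0, x1, y1), half-open


@dataclass
class SyntheticDataset:
    config: SynthConfig
    records: list[SynthRecord]
    manifest: pd.DataFrame
    out_dir: Path | None = None


def default_counts(taxonomy: DiseaseTaxonomy, total: int = 600, ratio: float = 10.0) -> dict[str, int]:
    """Geometric class-count spread with largest:smallest ~= ``ratio``.

    Mirrors the long-tailed class distribution of clinical screening datasets
    and gives the focal loss an imbalance to work against.
    """
    ids = taxonomy.class_order[2]
    k = len(ids)
    raw = np.array([ratio ** (-(i / max(k - 1, 1))) for i in range(k)])
    counts = np.maximum(1, np.round(raw / raw.sum() * total).astype(int))
    return dict(zip(ids, counts.tolist()))


def desk_config(seed: int = 42, total: int = 600, image_size: int = 96) -> SynthConfig:
    """Desk-scale study conditions: 2x4-class fixture, 10:1 imbalance, 10% composites."""
    tax = bundled_taxonomy("desk")
    return SynthConfig(
        taxonomy=tax,
        image_size=image_size,
        n_per_class=default_counts(tax, total=total),
        composite_fraction=0.1,
        noise_sd=0.02,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# drawing primitives (all in float [0,1], HWC)

def _hsv(h: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(h % 1.0, s, v), dtype=np.float64)


def _level1_hue(taxonomy: DiseaseTaxonomy, l1_id: str) -> float:
    order = taxonomy.class_order[1]
    i = order.index(l1_id)
    return (i / len(order) + 0.075) % 1.0


_MOTIFS = ("disc", "ring", "square", "diamond")


def _paint_background(img: np.ndarray, x0: int, x1: int, taxonomy, l1_id: str) -> None:
    """Fill columns [x0, x1) with the level-1 hue band and centred motif."""
    h, w = img.shape[:2]
    hue = _level1_hue(taxonomy, l1_id)
    img[:, x0:x1] = _hsv(hue, 0.55, 0.75)
    # vertical brightness gradient for mild within-class variation structure
    grad = np.linspace(-0.06, 0.06, h)[:, None, None]
    img[:, x0:x1] = np.clip(img[:, x0:x1] + grad, 0, 1)
    motif = _MOTIFS[taxonomy.class_order[1].index(l1_id) % len(_MOTIFS)]
    cx, cy = (x0 + x1) // 2, h // 2
    r = int(0.27 * min(x1 - x0, h))
    yy, xx = np.mgrid[0:h, 0:w]
    if motif == "disc":
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    elif motif == "ring":
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = (d2 <= r * r) & (d2 >= (0.6 * r) ** 2)
    elif motif == "square":
        mask = (np.abs(xx - cx) <= r) & (np.abs(yy - cy) <= r)
    else:  # diamond
        mask = (np.abs(xx - cx) + np.abs(yy - cy)) <= r
    mask &= (xx >= x0) & (xx < x1)
    img[mask] = _hsv(hue, 0.85, 0.4)


def _lesion_style(taxonomy: DiseaseTaxonomy, l2_id: str) -> tuple[str, int]:
    """(orientation, cycles-per-box) of a subclass's stripe texture."""
    node = taxonomy.node(l2_id)
    siblings = [c for c in taxonomy.class_order[2] if taxonomy.node(c).parent_id == node.parent_id]
    j = siblings.index(l2_id)
    orient = "vertical" if j % 2 == 0 else "horizontal"
    return orient, 3 + 2 * (j // 2)


def _paint_lesion(img: np.ndarray, box: tuple[int, int, int, int], taxonomy, l2_id: str) -> None:
    x0, y0, x1, y1 = box
    orient, cycles = _lesion_style(taxonomy, l2_id)
    side_x, side_y = x1 - x0, y1 - y0
    yy, xx = np.mgrid[0:side_y, 0:side_x]
    u = xx / side_x if orient == "vertical" else yy / side_y
    stripes = np.sign(np.sin(2 * np.pi * cycles * u)) >= 0
    patch = np.where(stripes[..., None], 0.95, 0.08)
    img[y0:y1, x0:x1] = patch


def _place_box(rng: np.random.Generator, side: int, x_lo: int, x_hi: int, h: int) -> tuple[int, int, int, int]:
    x0 = int(rng.integers(x_lo, x_hi - side + 1))
    y0 = int(rng.integers(0, h - side + 1))
    return (x0, y0, x0 + side, y0 + side)


def _render(
    config: SynthConfig, rng: np.random.Generator, level2_ids: list[str]
) -> tuple[np.ndarray, dict[str, tuple[int, int, int, int]]]:
    """Render one image for the given (1 or 2) level-2 labels."""
    tax = config.taxonomy
    s = config.image_size
    side = max(8, int(round(config.lesion_fraction * s)))
    img = np.zeros((s, s, 3), dtype=np.float64)
    parents = [tax.node(c).parent_id for c in level2_ids]
    boxes: dict[str, tuple[int, int, int, int]] = {}
    if len(level2_ids) == 1 or parents[0] == parents[1]:
        _paint_background(img, 0, s, tax, parents[0])
        spans = [(0, s)] * len(level2_ids)
    else:
        # composite across coarse groups: split the canvas, one hue band each
        half = s // 2
        _paint_background(img, 0, half, tax, parents[0])
        _paint_background(img, half, s, tax, parents[1])
        spans = [(0, half), (half, s)]
    for cid, (x_lo, x_hi) in zip(level2_ids, spans):
        for _ in range(20):  # avoid overlapping lesions where possible
            box = _place_box(rng, side, x_lo, x_hi, s)
            if all(_no_overlap(box, other) for other in boxes.values()):
                break
        boxes[cid] = box
        _paint_lesion(img, box, tax, cid)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0), boxes


def _no_overlap(a, b) -> bool:
    return a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]


# ---------------------------------------------------------------------------
# dataset generation

def _draw_label_sets(config: SynthConfig, rng: np.random.Generator) -> list[list[str]]:
    order2 = config.taxonomy.class_order[2]
    primaries: list[str] = []
    for cid in order2:  # class_order fixes the draw order -> determinism
        primaries += [cid] * config.n_per_class.get(cid, 0)
    total = len(primaries)
    if total == 0:
        raise ValueError("n_per_class yields an empty dataset")
    n_comp = int(round(config.composite_fraction * total))
    comp_idx = set(rng.choice(total, size=n_comp, replace=False).tolist()) if n_comp else set()
    label_sets: list[list[str]] = []
    for i, cid in enumerate(primaries):
        if i in comp_idx and len(order2) > 1:
            others = [c for c in order2 if c != cid]
            second = others[int(rng.integers(len(others)))]
            label_sets.append([cid, second])
        else:
            label_sets.append([cid])
    perm = rng.permutation(total)
    return [label_sets[i] for i in perm]


def generate_arrays(config: SynthConfig) -> tuple[np.ndarray, list[SynthRecord]]:
    """Generate the dataset fully in memory: (images NHWC float32, records).

    ``image_path`` in the records is a symbolic name (``img_00000.png`` ...);
    :func:`generate_dataset` materializes the same pixels on disk.
    """
    rng = np.random.default_rng(config.seed)
    label_sets = _draw_label_sets(config, rng)
    images = np.empty(
        (len(label_sets), config.image_size, config.image_size, 3), dtype=np.float32
    )
    records: list[SynthRecord] = []
    for i, ids in enumerate(label_sets):
        img, boxes = _render(config, rng, ids)
        images[i] = img.astype(np.float32)
        records.append(
            SynthRecord(
                image_path=f"img_{i:05d}.png",
                label=expand_labels(config.taxonomy, ids),
                level2_ids=list(ids),
                lesion_boxes=boxes,
            )
        )
    return images, records


def records_to_manifest(records: list[SynthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_path": [r.image_path for r in records],
            "level2_labels": [";".join(r.level2_ids) for r in records],
            "lesion_boxes": [
                json.dumps({k: list(v) for k, v in r.lesion_boxes.items()})
                for r in records
            ],
        }
    )


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> SyntheticDataset:
    """Generate the dataset and write PNG images + ``manifest.csv`` to disk."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, records = generate_arrays(config)
    for img, rec in zip(images, records):
        rel = Path("images") / rec.image_path
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / rel)
        rec.image_path = str(rel)
    manifest = records_to_manifest(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return SyntheticDataset(config=config, records=records, manifest=manifest, out_dir=out_dir)


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def load_images(manifest: pd.DataFrame, root: str | Path) -> np.ndarray:
    """Read the manifest's PNG/JPEG images as an NHWC float32 array in [0, 1]."""
    root = Path(root)
    arrays = []
    for p in manifest["image_path"]:
        with Image.open(root / p) as im:
            arrays.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
    return np.stack(arrays)


def manifest_labels(manifest: pd.DataFrame, taxonomy: DiseaseTaxonomy) -> list[MultiLevelLabel]:
    return [
        expand_labels(taxonomy, str(s).split(";")) for s in manifest["level2_labels"]
    ]


def labels_to_matrices(
    labels: list[MultiLevelLabel], taxonomy: DiseaseTaxonomy
) -> dict[int, np.ndarray]:
    """Stack per-sample labels into per-level multi-hot matrices."""
    return {
        lvl: np.stack([lab.vec(lvl) for lab in labels]).astype(np.float32)
        for lvl in (1, 2)
    }


# ---------------------------------------------------------------------------
# partitioning

def train_test_partition(
    manifest: pd.DataFrame, fraction_test: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive split, stratified by the level-2 label set.

    Test counts are allocated per stratum by largest remainder so the overall
    test size equals ``round(fraction_test * n)``; any stratum with at least 5
    records is represented in both parts.
    """
    if not 0.0 < fraction_test < 1.0:
        raise ValueError("fraction_test must lie in (0, 1)")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    rng = np.random.default_rng(seed)
    n = len(manifest)
    target = int(round(fraction_test * n))
    groups: dict[str, list[int]] = {}
    for idx, key in enumerate(manifest["level2_labels"].astype(str)):
        groups.setdefault(key, []).append(idx)
    keys = sorted(groups)
    quota = {k: fraction_test * len(groups[k]) for k in keys}
    alloc = {k: int(np.floor(quota[k])) for k in keys}
    # keep at least one training record per stratum
    for k in keys:
        alloc[k] = min(alloc[k], len(groups[k]) - 1)
    remainder = target - sum(alloc.values())
    order = sorted(keys, key=lambda k: (quota[k] - np.floor(quota[k])), reverse=True)
    for k in order:
        if remainder <= 0:
            break
        if alloc[k] < len(groups[k]) - 1:
            alloc[k] += 1
            remainder -= 1
    # guarantee representation of non-tiny strata in the test part
    for k in keys:
        if len(groups[k]) >= 5 and alloc[k] == 0:
            donor = max(
                (d for d in keys if alloc[d] > max(1, int(np.floor(quota[d])))),
                key=lambda d: alloc[d],
                default=None,
            )
            alloc[k] = 1
            if donor is not None:
                alloc[donor] -= 1
    test_idx: list[int] = []
    for k in keys:
        members = np.array(groups[k])
        pick = rng.choice(len(members), size=alloc[k], replace=False)
        test_idx += members[pick].tolist()
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    train = manifest.loc[~test_mask].reset_index(drop=True)
    test = manifest.loc[test_mask].reset_index(drop=True)
    return train, test
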