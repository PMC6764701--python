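"""Synthetic embryo-style image corpora with a planted regulatory network.

The generator emulates the structure of standardized in-situ-hybridization
(ISH) image collections: every gene owns a variable-size set of grayscale
images per viewing orientation (lateral / ventral / dorsal), rendered as
dark staining on a light elliptical "embryo" against a white background.

The planted signal mimics the biology that motivates image-pair learning:
a TF and its target share *local* expression territories (one or more
common active regions) while their *global* intensity levels may differ by
a per-gene multiplicative scale.  Certified negative pairs share no active
region.  Global-image similarity is therefore deliberately uninformative;
only local co-expression separates the classes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

ORIENTATIONS = ("lateral", "ventral", "dorsal")

__all__ = [
    "ORIENTATIONS", "SyntheticSpec", "SyntheticCorpus", "CorpusImage",
    "generate_corpus", "write_corpus", "region_center", "region_bbox",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic corpus.

    ``images_per_gene_per_orientation`` is an inclusive ``(lo, hi)`` range;
    a lower bound of 0 is allowed but every gene is guaranteed at least one
    image overall.  ``global_scale_range`` multiplies each gene's staining
    amplitude, decoupling whole-image intensity from the local pattern.
    ``noise_sd`` is in 8-bit intensity units.
    """

    n_tfs: int = 8
    n_targets: int = 24
    n_regions: int = 4
    img_width: int = 320
    img_height: int = 128
    images_per_gene_per_orientation: tuple[int, int] = (1, 2)
    interaction_density: float = 0.18
    noise_sd: float = 4.0
    global_scale_range: tuple[float, float] = (0.6, 2.4)
    active_regions_per_gene: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_tfs < 1 or self.n_targets < 1:
            raise ValueError("need at least one TF and one target gene")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2 so that edge and non-edge "
                             "pairs are distinguishable by region overlap")
        lo, hi = self.images_per_gene_per_orientation
        if lo < 0 or hi < lo:
            raise ValueError("images_per_gene_per_orientation must be a "
                             "non-negative inclusive range (lo <= hi)")
        if hi == 0:
            raise ValueError("every gene needs at least one image in some orientation")
        if not 0.0 < self.interaction_density < 1.0:
            raise ValueError("interaction_density must lie in (0, 1)")
        if not 1 <= self.active_regions_per_gene < self.n_regions:
            raise ValueError("active_regions_per_gene must be in [1, n_regions)")
        if self.img_width < 16 or self.img_height < 16:
            raise ValueError("images must be at least 16x16 pixels")

    @property
    def tf_ids(self) -> list[str]:
        return [f"tf{i:03d}" for i in range(self.n_tfs)]

    @property
    def target_ids(self) -> list[str]:
        return [f"tg{i:03d}" for i in range(self.n_targets)]


@dataclass(frozen=True)
class CorpusImage:
    gene_id: str
    orientation: str
    index: int
    pixels: np.ndarray  # uint8, (img_height, img_width)


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    images: list[CorpusImage]
    truth_edges: set[tuple[str, str]]
    certified_negatives: set[tuple[str, str]]
    # pairs that share a region but were not planted as edges -- the analogue
    # of a partially-supported ("medium confidence") link set
    medium_edges: set[tuple[str, str]]
    region_assignments: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def images_of(self, gene_id: str, orientation: str) -> list[CorpusImage]:
        return [im for im in self.images
                if im.gene_id == gene_id and im.orientation == orientation]


# ---------------------------------------------------------------------------
# region geometry: a fixed anatomical-style layout per orientation, so the
# same region index maps to different coordinates in different orientations.

_ORIENT_PHASE = {"lateral": 0.0, "ventral": 2.0 * np.pi / 3.0,
                 "dorsal": 4.0 * np.pi / 3.0}


def region_center(orientation: str, region: int, n_regions: int,
                  height: int, width: int) -> tuple[float, float]:
    """(row, col) center of a region inside the elliptical embryo."""
    phase = _ORIENT_PHASE[orientation]
    t = 2.0 * np.pi * region / n_regions + phase
    # regions sit on an inner ellipse so blobs stay inside the embryo
    r0, c0 = height / 2.0, width / 2.0
    row = r0 + 0.55 * (height / 2.0) * np.sin(t)
    col = c0 + 0.70 * (width / 2.0) * np.cos(t)
    return row, col


def _region_sigma(height: int, width: int) -> float:
    return max(2.0, 0.11 * min(height, width))


def region_bbox(orientation: str, region: int, n_regions: int,
                height: int, width: int, n_sigma: float = 2.5
                ) -> tuple[int, int, int, int]:
    """(row0, col0, row1, col1) inclusive-exclusive box around a region."""
    row, col = region_center(orientation, region, n_regions, height, width)
    s = n_sigma * _region_sigma(height, width)
    return (max(0, int(row - s)), max(0, int(col - s)),
            min(height, int(row + s) + 1), min(width, int(col + s) + 1))


def _embryo_mask(height: int, width: int) -> np.ndarray:
    rr, cc = np.mgrid[0:height, 0:width]
    return (((rr - height / 2.0) / (0.46 * height)) ** 2
            + ((cc - width / 2.0) / (0.47 * width)) ** 2) <= 1.0


def _render_image(spec: SyntheticSpec, regions: tuple[int, ...],
                  orientation: str, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    h, w = spec.img_height, spec.img_width
    sigma = _region_sigma(h, w)
    stain = np.zeros((h, w), dtype=np.float64)
    for r in regions:
        row, col = region_center(orientation, r, spec.n_regions, h, w)
        impulse = np.zeros((h, w))
        impulse[int(round(row)) % h, int(round(col)) % w] = 1.0
        blob = ndimage.gaussian_filter(impulse, sigma, mode="constant")
        stain += blob / blob.max()
    jitter = rng.uniform(0.9, 1.1)  # per-image staining-batch variation
    img = np.full((h, w), 255.0)
    mask = _embryo_mask(h, w)
    img[mask] = 232.0 - np.clip(amplitude * jitter * stain[mask], 0.0, 220.0)
    img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a corpus with planted TF->target edges.

    Deterministic given ``spec.seed``.  Positives share at least one active
    region; certified negatives share none.  Raises ``ValueError`` naming
    the shared-region constraint when the requested edge count cannot be
    sampled.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = spec.tf_ids + spec.target_ids
    regions: dict[str, tuple[int, ...]] = {}
    for g in genes:
        regions[g] = tuple(sorted(rng.choice(spec.n_regions,
                                             size=spec.active_regions_per_gene,
                                             replace=False).tolist()))

    sharing = [(t, g) for t in spec.tf_ids for g in spec.target_ids
               if set(regions[t]) & set(regions[g])]
    disjoint = [(t, g) for t in spec.tf_ids for g in spec.target_ids
                if not (set(regions[t]) & set(regions[g]))]

    n_edges = int(round(spec.interaction_density * spec.n_tfs * spec.n_targets))
    if len(sharing) < n_edges:
        raise ValueError(
            f"cannot plant {n_edges} edges: only {len(sharing)} TF-target pairs "
            "satisfy the shared-active-region constraint; increase "
            "active_regions_per_gene or decrease n_regions/interaction_density")
    order = rng.permutation(len(sharing))
    truth = {sharing[i] for i in order[:n_edges]}
    medium = {sharing[i] for i in order[n_edges:]}

    images: list[CorpusImage] = []
    lo, hi = spec.images_per_gene_per_orientation
    for g in genes:
        amplitude = 110.0 * rng.uniform(*spec.global_scale_range)
        counts = rng.integers(lo, hi + 1, size=3)
        if counts.sum() == 0:
            counts[rng.integers(0, 3)] = max(1, lo)
        for orient, k in zip(ORIENTATIONS, counts):
            for idx in range(int(k)):
                images.append(CorpusImage(
                    gene_id=g, orientation=orient, index=idx,
                    pixels=_render_image(spec, regions[g], orient, amplitude, rng)))

    return SyntheticCorpus(
        spec=spec, images=images, truth_edges=truth,
        certified_negatives=set(disjoint), medium_edges=medium,
        region_assignments=regions)


# ---------------------------------------------------------------------------
# on-disk layout


def _edge_tsv(path: Path, edges: set[tuple[str, str]]) -> None:
    lines = ["tf_id\ttarget_id"] + [f"{t}\t{g}" for t, g in sorted(edges)]
    path.write_text("\n".join(lines) + "\n")


def write_corpus(corpus: SyntheticCorpus, out_dir) -> dict:
    """Write PNGs, edge-list TSVs and a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    img_dir = out / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create corpus directory {out}: {e}") from e

    entries = []
    for im in corpus.images:
        fname = f"{im.gene_id}_{im.orientation}_{im.index:02d}.png"
        path = img_dir / fname
        try:
            Image.fromarray(im.pixels, mode="L").save(path, format="PNG")
        except OSError as e:
            raise OSError(f"failed writing image {path}: {e}") from e
        entries.append({
            "file": f"images/{fname}",
            "gene_id": im.gene_id,
            "orientation": im.orientation,
            "index": im.index,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        })

    _edge_tsv(out / "truth_edges.tsv", corpus.truth_edges)
    _edge_tsv(out / "certified_negatives.tsv", corpus.certified_negatives)
    _edge_tsv(out / "medium_edges.tsv", corpus.medium_edges)

    manifest = {
        "img_height": corpus.spec.img_height,
        "img_width": corpus.spec.img_width,
        "n_images": len(entries),
        "images": entries,
        "edge_files": {
            "truth": "truth_edges.tsv",
            "certified_negatives": "certified_negatives.tsv",
            "medium": "medium_edges.tsv",
        },
        "region_assignments": {g: list(r)
                               for g, r in sorted(corpus.region_assignments.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
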