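"""Corpus loading, pair labeling, negative sampling and gene-level splitting.

The supervision unit is a labeled TF->target gene pair.  Because every gene
owns a *set* of images per orientation, a pair of genes is reduced to all
orientation-matched cross-products of single images (multi-instance to
single-instance reduction); every image-pair instance inherits the gene
pair's label.  Splitting is done at the gene level: images of one gene
never appear on both sides of the train/test divide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .simulate import ORIENTATIONS

__all__ = [
    "GeneImageSet", "GenePairLabel", "ImagePairInstance", "SplitPlan",
    "load_corpus", "image_sets_from_corpus", "read_edge_tsv",
    "sample_negatives", "split_by_gene", "enumerate_instances",
    "instance_count", "write_instance_index",
]


@dataclass
class GeneImageSet:
    """All images of one gene, partitioned by viewing orientation."""

    gene_id: str
    by_orientation: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def count(self, orientation: str) -> int:
        return len(self.by_orientation.get(orientation, []))

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_orientation.values())

    def image(self, orientation: str, index: int) -> np.ndarray:
        return self.by_orientation[orientation][index]


@dataclass(frozen=True)
class GenePairLabel:
    tf_id: str
    target_id: str
    label: int  # 1 = regulatory link, 0 = no link
    provenance: str = "high_confidence"  # | sampled_negative | medium_confidence

    def __post_init__(self):
        if self.tf_id == self.target_id:
            raise ValueError(f"self-pair {self.tf_id} is not a valid TF-target pair")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.tf_id, self.target_id)


@dataclass(frozen=True)
class ImagePairInstance:
    """One orientation-matched (TF image, target image) pair.

    Image references are (gene_id, orientation, index) into the loaded
    image sets; the TF image is always the first member and sits on top of
    the concatenated model input (the order is a hard contract — reversing
    it measurably changes predictions).
    """

    tf_image: tuple[str, str, int]
    target_image: tuple[str, str, int]
    orientation: str
    label: int
    pair: GenePairLabel


@dataclass
class SplitPlan:
    train_pairs: list[GenePairLabel]
    val_pairs: list[GenePairLabel]
    test_pairs: list[GenePairLabel]
    train_genes: frozenset[str]
    test_genes: frozenset[str]
    dropped_mixed: int
    split_seed: int
    achieved_train_frac: float
    retries: int

    def report(self) -> dict:
        n_tr, n_va, n_te = (len(self.train_pairs), len(self.val_pairs),
                            len(self.test_pairs))
        kept = n_tr + n_va + n_te
        return {
            "n_train_pairs": n_tr,
            "n_val_pairs": n_va,
            "n_test_pairs": n_te,
            "dropped_mixed_pairs": self.dropped_mixed,
            "achieved_train_frac": self.achieved_train_frac,
            "val_frac_of_train": (n_va / (n_tr + n_va)) if (n_tr + n_va) else 0.0,
            "test_frac": (n_te / kept) if kept else 0.0,
            "n_train_genes": len(self.train_genes),
            "n_test_genes": len(self.test_genes),
            "split_seed": self.split_seed,
            "retries": self.retries,
        }


# ---------------------------------------------------------------------------
# I/O


def load_corpus(image_dir, manifest_path) -> dict[str, GeneImageSet]:
    """Read a manifest + image directory into per-gene image sets.

    Errors name the offending manifest row: missing files, unknown
    orientation tokens and inconsistent image dimensions are all rejected.
    """
    image_dir = Path(image_dir)
    manifest = json.loads(Path(manifest_path).read_text())
    sets: dict[str, GeneImageSet] = {}
    dims: tuple[int, int] | None = None
    for row_no, entry in enumerate(manifest["images"]):
        orient = entry["orientation"]
        if orient not in ORIENTATIONS:
            raise ValueError(f"manifest row {row_no}: unknown orientation "
                             f"{orient!r} (expected one of {ORIENTATIONS})")
        path = image_dir / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"manifest row {row_no}: missing image {path}")
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
        if dims is None:
            dims = arr.shape
        elif arr.shape != dims:
            raise ValueError(f"manifest row {row_no}: image {path} has shape "
                             f"{arr.shape}, expected {dims}")
        gs = sets.setdefault(entry["gene_id"], GeneImageSet(entry["gene_id"]))
        gs.by_orientation.setdefault(orient, []).append(arr)
    return sets


def image_sets_from_corpus(corpus) -> dict[str, GeneImageSet]:
    """In-memory view of a SyntheticCorpus, bypassing the PNG round trip."""
    sets: dict[str, GeneImageSet] = {}
    for im in corpus.images:
        gs = sets.setdefault(im.gene_id, GeneImageSet(im.gene_id))
        gs.by_orientation.setdefault(im.orientation, []).append(im.pixels)
    return sets


def read_edge_tsv(path) -> set[tuple[str, str]]:
    edges = set()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[0].strip() != "tf_id":
            raise ValueError(f"{path}: expected header 'tf_id<TAB>target_id', "
                             f"got {header.strip()!r}")
        for line in fh:
            line = line.strip()
            if line:
                tf, tg = line.split("\t")[:2]
                edges.add((tf, tg))
    return edges


# ---------------------------------------------------------------------------
# pair construction


def sample_negatives(tf_universe, gene_universe, positives, exclusion,
                     ratio: float, seed: int) -> list[GenePairLabel]:
    """Uniform negative pairs from TF x gene minus positives/exclusion/self.

    Returns ``ceil(ratio * |positives|)`` distinct pairs (the published
    protocol uses ratio 1.0: as many negatives as verified links, none of
    which may appear in the high- or medium-confidence network).
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    n_needed = int(np.ceil(ratio * len(positives)))
    if n_needed == 0:
        return []
    forbidden = set(positives) | set(exclusion)
    pool = sorted((t, g) for t in tf_universe for g in gene_universe
                  if t != g and (t, g) not in forbidden)
    if len(pool) < n_needed:
        raise ValueError(f"cannot sample {n_needed} negatives: only "
                         f"{len(pool)} candidate pairs available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_needed, replace=False)
    return [GenePairLabel(*pool[i], label=0, provenance="sampled_negative")
            for i in sorted(idx)]


def instance_count(pair: GenePairLabel, tf_set: GeneImageSet,
                   target_set: GeneImageSet) -> int:
    return sum(tf_set.count(o) * target_set.count(o) for o in ORIENTATIONS)


def enumerate_instances(pair: GenePairLabel, tf_set: GeneImageSet,
                        target_set: GeneImageSet) -> list[ImagePairInstance]:
    """All orientation-matched cross-product image pairs for one gene pair.

    The list length is sum over orientations of |X_i,o| * |X_j,o|; an empty
    list (no shared non-empty orientation) marks the pair unscorable.
    """
    out: list[ImagePairInstance] = []
    for o in ORIENTATIONS:
        for p in range(tf_set.count(o)):
            for q in range(target_set.count(o)):
                out.append(ImagePairInstance(
                    tf_image=(pair.tf_id, o, p),
                    target_image=(pair.target_id, o, q),
                    orientation=o, label=pair.label, pair=pair))
    return out


# ---------------------------------------------------------------------------
# gene-level splitting


def _gene_odds(train_frac: float) -> float:
    # pair-level train:test odds r map to gene-level odds sqrt(r), because a
    # pair needs both endpoints on the same side and mixed pairs are dropped
    r = train_frac / (1.0 - train_frac)
    return np.sqrt(r) / (1.0 + np.sqrt(r))


def split_by_gene(pairs, train_frac: float = 0.8,
                  val_frac_of_train: float = 0.1, seed: int = 0,
                  tolerance: float = 0.05, max_retries: int = 200) -> SplitPlan:
    """Partition genes into train/test sides; assign pairs accordingly.

    A pair is a training pair iff both endpoints are train-genes and a test
    pair iff both are test-genes; mixed pairs are dropped (and counted).
    The gene-level fraction is chosen so the *pair*-level train fraction
    lands near ``train_frac``; reshuffles retry until it falls within
    ``tolerance``.  Validation pairs are then drawn from the training pairs
    at rate ``val_frac_of_train`` (their genes stay on the training side,
    so test genes remain untouched).
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0,1)")
    pairs = sorted(pairs, key=lambda p: p.key)
    genes = sorted({p.tf_id for p in pairs} | {p.target_id for p in pairs})
    g_frac = _gene_odds(train_frac)
    rng = np.random.default_rng(seed)

    best = None
    for attempt in range(max_retries):
        perm = rng.permutation(len(genes))
        n_train = int(round(g_frac * len(genes)))
        train_genes = frozenset(genes[i] for i in perm[:n_train])
        test_genes = frozenset(genes[i] for i in perm[n_train:])
        tr = [p for p in pairs
              if p.tf_id in train_genes and p.target_id in train_genes]
        te = [p for p in pairs
              if p.tf_id in test_genes and p.target_id in test_genes]
        kept = len(tr) + len(te)
        if kept == 0 or not tr or not te:
            continue
        achieved = len(tr) / kept
        cand = (abs(achieved - train_frac), attempt, achieved,
                train_genes, test_genes, tr, te)
        if best is None or cand[0] < best[0]:
            best = cand
        if cand[0] <= tolerance:
            break
    if best is None:
        raise ValueError("gene-level split failed: no shuffle yielded both "
                         "train and test pairs")
    dev, attempt, achieved, train_genes, test_genes, tr, te = best
    if dev > tolerance:
        raise ValueError(f"gene-level split failed after {max_retries} retries: "
                         f"best achieved train fraction {achieved:.3f} vs "
                         f"requested {train_frac:.3f} (tolerance {tolerance})")

    n_val = int(round(val_frac_of_train * len(tr)))
    vidx = set(rng.choice(len(tr), size=n_val, replace=False).tolist())
    val = [p for i, p in enumerate(tr) if i in vidx]
    tr = [p for i, p in enumerate(tr) if i not in vidx]
    dropped = len(pairs) - (len(tr) + len(val) + len(te))
    return SplitPlan(train_pairs=tr, val_pairs=val, test_pairs=te,
                     train_genes=train_genes, test_genes=test_genes,
                     dropped_mixed=dropped, split_seed=seed,
                     achieved_train_frac=achieved, retries=attempt)


def write_instance_index(instances, path) -> None:
    """TSV index of instances: tf_image, target_image, orientation, label."""
    lines = ["tf_image\ttarget_image\torientation\tlabel"]
    for ins in instances:
        tf = "/".join(map(str, ins.tf_image))
        tg = "/".join(map(str, ins.target_image))
        lines.append(f"{tf}\t{tg}\t{ins.orientation}\t{ins.label}")
    Path(path).write_text("\n".join(lines) + "\n")
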