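"""Pair construction, negative sampling, instance enumeration, gene-level split."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnpairs import (GenePairLabel, enumerate_instances, sample_negatives,
                      split_by_gene)
from grnpairs.dataset import (GeneImageSet, instance_count, load_corpus,
                              read_edge_tsv, write_instance_index)

ORIENTS = ("lateral", "ventral", "dorsal")


def make_set(gene, counts):
    img = np.zeros((4, 4), dtype=np.uint8)
    return GeneImageSet(gene, {o: [img] * n for o, n in zip(ORIENTS, counts)})


# ---------------------------------------------------------------------------
# loading


def test_load_corpus_groups_by_gene_and_orientation(tmp_path):
    from PIL import Image
    img_dir = tmp_path / "images"
    img_dir.mkdir()
    rows = []
    for i, orient in enumerate(["lateral", "lateral", "dorsal"]):
        f = f"geneA_{orient}_{i}.png"
        Image.fromarray(np.full((4, 6), 100, dtype=np.uint8), "L").save(img_dir / f)
        rows.append({"file": f"images/{f}", "gene_id": "geneA",
                     "orientation": orient, "index": i})
    (tmp_path / "manifest.json").write_text(json.dumps({"images": rows}))
    sets = load_corpus(tmp_path, tmp_path / "manifest.json")
    assert sets["geneA"].count("lateral") == 2
    assert sets["geneA"].count("ventral") == 0
    assert sets["geneA"].count("dorsal") == 1


def test_load_corpus_rejects_unknown_orientation(tmp_path):
    (tmp_path / "manifest.json").write_text(json.dumps(
        {"images": [{"file": "x.png", "gene_id": "g", "orientation": "frontal",
                     "index": 0}]}))
    with pytest.raises(ValueError, match="row 0.*frontal"):
        load_corpus(tmp_path, tmp_path / "manifest.json")


def test_load_corpus_rejects_missing_file(tmp_path):
    (tmp_path / "manifest.json").write_text(json.dumps(
        {"images": [{"file": "nope.png", "gene_id": "g",
                     "orientation": "lateral", "index": 0}]}))
    with pytest.raises(FileNotFoundError, match="row 0"):
        load_corpus(tmp_path, tmp_path / "manifest.json")


def test_load_corpus_rejects_inconsistent_dimensions(tmp_path):
    from PIL import Image
    Image.fromarray(np.zeros((4, 6), np.uint8), "L").save(tmp_path / "a.png")
    Image.fromarray(np.zeros((5, 6), np.uint8), "L").save(tmp_path / "b.png")
    (tmp_path / "manifest.json").write_text(json.dumps({"images": [
        {"file": "a.png", "gene_id": "g", "orientation": "lateral", "index": 0},
        {"file": "b.png", "gene_id": "h", "orientation": "lateral", "index": 0},
    ]}))
    with pytest.raises(ValueError, match="row 1"):
        load_corpus(tmp_path, tmp_path / "manifest.json")


def test_empty_manifest_gives_empty_collection(tmp_path):
    (tmp_path / "manifest.json").write_text(json.dumps({"images": []}))
    assert load_corpus(tmp_path, tmp_path / "manifest.json") == {}


def test_edge_tsv_roundtrip(tmp_path):
    edges = {("tf1", "g1"), ("tf2", "g9")}
    (tmp_path / "e.tsv").write_text(
        "tf_id\ttarget_id\n" + "\n".join(f"{a}\t{b}" for a, b in sorted(edges)))
    assert read_edge_tsv(tmp_path / "e.tsv") == edges


# ---------------------------------------------------------------------------
# negative sampling


def test_negatives_match_count_and_avoid_positives_and_exclusion():
    tfs = [f"t{i}" for i in range(4)]
    genes = [f"g{i}" for i in range(20)]
    positives = {("t0", "g0"), ("t1", "g1"), ("t2", "g2")}
    exclusion = {("t3", "g3")}
    negs = sample_negatives(tfs, genes, positives, exclusion, 2.0, seed=1)
    assert len(negs) == 6
    keys = {n.key for n in negs}
    assert len(keys) == 6
    assert not keys & (positives | exclusion)
    assert all(n.label == 0 and n.provenance == "sampled_negative" for n in negs)


def test_negative_sampling_deterministic_and_seed_sensitive():
    args = (["t0", "t1"], [f"g{i}" for i in range(30)],
            {("t0", "g0")} , set())
    a = sample_negatives(*args, ratio=5.0, seed=3)
    b = sample_negatives(*args, ratio=5.0, seed=3)
    c = sample_negatives(*args, ratio=5.0, seed=4)
    assert [x.key for x in a] == [x.key for x in b]
    assert [x.key for x in a] != [x.key for x in c]


def test_zero_ratio_gives_empty_set():
    assert sample_negatives(["t"], ["g"], {("t", "g2")}, set(), 0.0, 0) == []


def test_infeasible_pool_reports_available_size():
    with pytest.raises(ValueError, match="only 2"):
        sample_negatives(["t0"], ["g0", "g1", "g2"],
                         {("t0", "g0"), ("x", "y"), ("p", "q"), ("r", "s"),
                          ("u", "v")},
                         set(), 1.0, 0)


# ---------------------------------------------------------------------------
# instance enumeration


def test_instance_enumeration_matches_worked_example():
    tf = make_set("tf", (2, 1, 0))
    tg = make_set("tg", (3, 0, 2))
    pair = GenePairLabel("tf", "tg", 1)
    ins = enumerate_instances(pair, tf, tg)
    assert len(ins) == 6  # 2*3 + 1*0 + 0*2
    assert all(i.label == 1 for i in ins)
    assert all(i.tf_image[0] == "tf" and i.target_image[0] == "tg" for i in ins)
    assert all(i.tf_image[1] == i.target_image[1] == i.orientation for i in ins)


def test_no_shared_orientation_yields_empty_list():
    ins = enumerate_instances(GenePairLabel("a", "b", 0),
                              make_set("a", (1, 0, 0)), make_set("b", (0, 2, 0)))
    assert ins == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(counts_tf=st.tuples(*[st.integers(0, 4)] * 3),
       counts_tg=st.tuples(*[st.integers(0, 4)] * 3),
       label=st.integers(0, 1))
def test_instance_count_identity_and_label_inheritance(counts_tf, counts_tg, label):
    """|instances| == sum_o |X_i,o| * |X_j,o|, every label inherited."""
    tf, tg = make_set("tf", counts_tf), make_set("tg", counts_tg)
    pair = GenePairLabel("tf", "tg", label)
    ins = enumerate_instances(pair, tf, tg)
    expected = sum(a * b for a, b in zip(counts_tf, counts_tg))
    assert len(ins) == expected == instance_count(pair, tf, tg)
    assert all(i.label == label and i.pair is pair for i in ins)
    # the full cross product, no duplicates
    assert len({(i.tf_image, i.target_image) for i in ins}) == len(ins)


def test_instance_index_tsv(tmp_path):
    ins = enumerate_instances(GenePairLabel("tf", "tg", 1),
                              make_set("tf", (1, 0, 0)), make_set("tg", (2, 0, 0)))
    write_instance_index(ins, tmp_path / "idx.tsv")
    lines = (tmp_path / "idx.tsv").read_text().strip().split("\n")
    assert lines[0] == "tf_image\ttarget_image\torientation\tlabel"
    assert len(lines) == 3


# ---------------------------------------------------------------------------
# gene-level split


def _many_pairs(n_tfs=16, n_tgs=48, density=0.25, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for t in range(n_tfs):
        for g in range(n_tgs):
            if rng.random() < density:
                pairs.append(GenePairLabel(f"t{t}", f"g{g}",
                                           int(rng.random() < 0.5)))
    return pairs


def test_split_hits_requested_fractions():
    pairs = _many_pairs()
    plan = split_by_gene(pairs, 0.8, 0.1, seed=2)
    rep = plan.report()
    assert abs(rep["achieved_train_frac"] - 0.8) <= 0.05
    assert abs(rep["val_frac_of_train"] - 0.1) <= 0.05
    kept = rep["n_train_pairs"] + rep["n_val_pairs"] + rep["n_test_pairs"]
    assert kept + rep["dropped_mixed_pairs"] == len(pairs)


def test_split_is_deterministic():
    pairs = _many_pairs()
    a = split_by_gene(pairs, 0.8, 0.1, seed=9)
    b = split_by_gene(pairs, 0.8, 0.1, seed=9)
    assert [p.key for p in a.train_pairs] == [p.key for p in b.train_pairs]
    assert [p.key for p in a.test_pairs] == [p.key for p in b.test_pairs]
    assert a.train_genes == b.train_genes


def test_no_gene_leaks_between_train_and_test():
    """Exhaustive scan: no gene supplies images to both sides."""
    pairs = _many_pairs()
    plan = split_by_gene(pairs, 0.8, 0.1, seed=2)
    train_side = {g for p in plan.train_pairs + plan.val_pairs
                  for g in (p.tf_id, p.target_id)}
    test_side = {g for p in plan.test_pairs for g in (p.tf_id, p.target_id)}
    assert not train_side & test_side
    assert train_side <= plan.train_genes
    assert test_side <= plan.test_genes


def test_split_failure_reports_best_achieved():
    # two genes -> a single pair can never split into both sides
    pairs = [GenePairLabel("t0", "g0", 1)]
    with pytest.raises(ValueError, match="split failed"):
        split_by_gene(pairs, 0.8, 0.1, seed=0, max_retries=5)


def test_invalid_train_frac_rejected():
    with pytest.raises(ValueError, match="train_frac"):
        split_by_gene(_many_pairs(), 1.0, 0.1, seed=0)
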