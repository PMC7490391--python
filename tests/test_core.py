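import numpy as np
import pandas as pd
import pytest

from muskin import DNA, FeatureTable, TaxonomyTable
from muskin.core import (
    PARTIAL,
    SHARED_ALL,
    UNIQUE,
    category_fraction,
    collapse_taxonomy,
    core_partition_analysis,
    core_set,
    partition_core,
    top_taxa,
)


def _taxonomy(mapping):
    frame = pd.DataFrame(
        {"phylum": "P", "class": "C", "order": "O", "family": "F",
         "genus": pd.Series(mapping)})
    frame.index.name = "feature_id"
    return TaxonomyTable(frame)


# ---------------------------------------------------------------------------
# collapse_taxonomy
# ---------------------------------------------------------------------------

def test_collapse_single_genus_preserves_sums():
    table = FeatureTable(["f1", "f2", "f3"], ["s1", "s2"],
                         np.array([[1, 2], [3, 4], [5, 6]]), DNA)
    tax = _taxonomy({"f1": "gA", "f2": "gA", "f3": "gA"})
    out = collapse_taxonomy(table, tax, "genus")
    assert out.feature_ids == ["gA"]
    assert np.array_equal(out.counts, [[9, 12]])


def test_collapse_hand_summed():
    table = FeatureTable(["f1", "f2", "f3", "f4"], ["s1", "s2"],
                         np.array([[1, 0], [2, 5], [4, 1], [8, 3]]), DNA)
    tax = _taxonomy({"f1": "gA", "f2": "gB", "f3": "gA", "f4": "gB"})
    out = collapse_taxonomy(table, tax, "genus")
    expected = {"gA": [5, 1], "gB": [10, 8]}
    for taxon, row in expected.items():
        assert np.array_equal(out.counts[out.feature_ids.index(taxon)], row)


@pytest.mark.parametrize("level", ["phylum", "class", "order", "family", "genus"])
def test_collapse_conserves_column_sums(default_bundle, level):
    bundle, _ = default_bundle
    out = collapse_taxonomy(bundle.table_dna, bundle.taxonomy, level)
    assert np.array_equal(out.sample_sums(), bundle.table_dna.sample_sums())


def test_unclassified_pooled_under_parent():
    table = FeatureTable(["f1"], ["s1"], np.array([[4]]), DNA)
    tax = TaxonomyTable(pd.DataFrame(
        {"phylum": ["P1"], "class": ["C1"], "order": ["Unclassified"],
         "family": ["Unclassified"], "genus": ["Unclassified"]},
        index=pd.Index(["f1"], name="feature_id")))
    out = collapse_taxonomy(table, tax, "genus")
    assert out.feature_ids == ["Unclassified_class_C1"]


def test_unknown_level_rejected():
    table = FeatureTable(["f1"], ["s1"], np.array([[1]]), DNA)
    with pytest.raises(ValueError, match="unknown level"):
        collapse_taxonomy(table, _taxonomy({"f1": "g"}), "species")


def test_missing_taxonomy_record_rejected():
    table = FeatureTable(["f1", "f2"], ["s1"], np.array([[1], [2]]), DNA)
    with pytest.raises(ValueError, match="f2"):
        collapse_taxonomy(table, _taxonomy({"f1": "g"}), "genus")


# ---------------------------------------------------------------------------
# top_taxa
# ---------------------------------------------------------------------------

def _group_table(label, taxa, columns):
    return FeatureTable(taxa, [f"{label}{j}" for j in range(len(columns[0]))],
                        np.array(columns), DNA)


def test_three_taxa_all_qualify_with_k5():
    taxa = ["t1", "t2", "t3"]
    table = _group_table("a", taxa, [[5, 5], [3, 3], [2, 2]])
    out = top_taxa({"g1": table, "g2": table}, k=5, min_groups=2)
    assert set(out) == set(taxa)


def test_top5_in_single_group_excluded():
    taxa = [f"t{i}" for i in range(6)]
    base = np.diag([60, 50, 40, 30, 20, 10]) + 1
    tables = {}
    for g in range(4):
        cols = np.roll(base, g, axis=0)
        tables[f"g{g}"] = _group_table(f"g{g}", taxa, cols)
    # construct a taxon dominant in exactly one group
    taxa2 = ["x", "y", "z", "u", "v", "w"]
    cols_a = [[100], [50], [40], [30], [20], [1]]
    cols_b = [[1], [50], [40], [30], [20], [100]]
    tables = {"ga": _group_table("a", taxa2, cols_a),
              "gb": _group_table("b", taxa2, cols_b),
              "gc": _group_table("c", taxa2, cols_b),
              "gd": _group_table("d", taxa2, cols_b)}
    out = top_taxa(tables, k=5, min_groups=2)
    assert "x" not in out  # top-5 only in ga
    assert "y" in out


def test_top_taxa_matches_bruteforce():
    rng = np.random.default_rng(0)
    taxa = [f"t{i}" for i in range(6)]
    tables = {f"g{j}": _group_table(f"g{j}", taxa,
                                    rng.integers(1, 100, size=(6, 4)))
              for j in range(3)}
    k, min_groups = 2, 2
    out = set(top_taxa(tables, k=k, min_groups=min_groups))

    # independent brute force over group means
    counts = {t: 0 for t in taxa}
    for table in tables.values():
        means = table.relative_abundance().mean(axis=1)
        order = sorted(zip(taxa, means), key=lambda p: (-p[1], p[0]))
        for t, _ in order[:k]:
            counts[t] += 1
    expected = {t for t, c in counts.items() if c >= min_groups}
    assert out == expected


def test_too_few_groups_rejected():
    table = _group_table("a", ["t1"], [[1]])
    with pytest.raises(ValueError, match="groups"):
        top_taxa({"g1": table}, min_groups=2)


# ---------------------------------------------------------------------------
# core_set
# ---------------------------------------------------------------------------

def test_exact_quarter_prevalence_included():
    counts = np.zeros((1, 12), dtype=int)
    counts[0, :3] = 7  # 3/12 = 25%
    table = FeatureTable(["t"], [f"s{i}" for i in range(12)], counts, DNA)
    assert core_set(table, table.sample_ids) == {"t"}


def test_below_prevalence_excluded():
    counts = np.zeros((1, 12), dtype=int)
    counts[0, :2] = 7  # 2/12 = 16.7%
    table = FeatureTable(["t"], [f"s{i}" for i in range(12)], counts, DNA)
    assert core_set(table, table.sample_ids) == set()


def test_single_sample_group_core_is_everything_present():
    table = FeatureTable(["a", "b", "c"], ["s1"], np.array([[1], [0], [9]]), DNA)
    assert core_set(table, ["s1"]) == {"a", "c"}


# ---------------------------------------------------------------------------
# partition_core
# ---------------------------------------------------------------------------

def test_identical_cores_all_shared():
    cores = {g: {"a", "b"} for g in ("g1", "g2", "g3")}
    partition = partition_core(cores)
    assert partition.taxa(SHARED_ALL) == {"a", "b"}
    assert partition.taxa(UNIQUE) == set()


def test_disjoint_cores_all_unique():
    partition = partition_core({"g1": {"a"}, "g2": {"b"}, "g3": {"c"}})
    assert partition.taxa(UNIQUE) == {"a", "b", "c"}
    assert partition.taxa(SHARED_ALL) == set()


def test_four_group_venn_with_17_shared():
    shared = {f"sh{i}" for i in range(17)}
    cores = {
        "g1": shared | {"u1", "p12"},
        "g2": shared | {"u2", "p12", "p234"},
        "g3": shared | {"u3", "p234"},
        "g4": shared | {"u4", "p234"},
    }
    partition = partition_core(cores)
    assert len(partition.taxa(SHARED_ALL)) == 17
    assert partition.taxa(UNIQUE) == {"u1", "u2", "u3", "u4"}
    assert partition.taxa(PARTIAL) == {"p12", "p234"}


def test_partition_invariant_to_group_order():
    cores = {"g1": {"a", "b"}, "g2": {"b", "c"}, "g3": {"a", "b", "c"}}
    forward = partition_core(cores)
    backward = partition_core(dict(reversed(list(cores.items()))))
    assert forward.categories == backward.categories


# ---------------------------------------------------------------------------
# category_fraction
# ---------------------------------------------------------------------------

def test_single_category_fraction_one():
    table = FeatureTable(["a", "b"], ["s1", "s2"],
                         np.array([[3, 5], [7, 2]]), DNA)
    partition = partition_core({"g1": {"a", "b"}, "g2": {"a", "b"}})
    fractions = category_fraction(table, ["s1", "s2"], partition, "g1")
    assert fractions[SHARED_ALL] == pytest.approx(1.0)
    assert fractions[UNIQUE] == 0.0


def test_hand_computed_30_70_split():
    table = FeatureTable(["sh", "un"], ["s1", "s2", "s3"],
                         np.array([[30, 30, 30], [70, 70, 70]]), DNA)
    partition = partition_core({"g1": {"sh", "un"}, "g2": {"sh"}})
    fractions = category_fraction(table, ["s1", "s2", "s3"], partition, "g1")
    assert fractions[SHARED_ALL] == pytest.approx(0.3)
    assert fractions[UNIQUE] == pytest.approx(0.7)


def test_fractions_sum_to_one_per_group(default_bundle):
    bundle, _ = default_bundle
    groups = {g: bundle.metadata.group_samples(g)
              for g in ("wild", "HL-Lab", "MPI-Lab", "C57BL/6J")}
    collapsed = collapse_taxonomy(
        bundle.table_dna.subset_samples(
            [s for ss in groups.values() for s in ss]),
        bundle.taxonomy, "genus")
    partition = core_partition_analysis(collapsed, groups)
    for g, fractions in partition.fractions.items():
        assert sum(fractions.values()) == pytest.approx(1.0)


def test_empty_core_flagged():
    table = FeatureTable(["a"], ["s1"], np.array([[1]]), DNA)
    partition = partition_core({"g1": {"a"}, "g2": set()})
    partition.core_by_group["g1"] = set()
    with pytest.raises(ValueError, match="empty core"):
        category_fraction(table, ["s1"], partition, "g1")


# ---------------------------------------------------------------------------
# commutation + recovery
# ---------------------------------------------------------------------------

def test_collapse_then_core_matches_membership_oracle(default_bundle):
    # core at genus level == prevalence of "any member feature present",
    # computed independently from the raw feature table
    bundle, _ = default_bundle
    wild = bundle.metadata.group_samples("wild")
    collapsed = collapse_taxonomy(bundle.table_dna, bundle.taxonomy, "genus")
    via_collapse = core_set(collapsed, wild)

    raw = bundle.table_dna.subset_samples(wild)
    members: dict = {}
    for f in raw.feature_ids:
        members.setdefault(bundle.taxonomy.label_at(f, "genus"), []).append(
            raw.feature_ids.index(f))
    oracle = set()
    for taxon, rows in members.items():
        present = (raw.counts[rows, :] > 0).any(axis=0)
        if present.mean() >= 0.25:
            oracle.add(taxon)
    assert via_collapse == oracle


def test_planted_shared_core_classified_shared(default_bundle):
    bundle, truth = default_bundle
    groups = {g: bundle.metadata.group_samples(g)
              for g in ("wild", "HL-Lab", "MPI-Lab", "C57BL/6J")}
    table = bundle.table_dna.subset_samples(
        [s for ss in groups.values() for s in ss])
    partition = core_partition_analysis(table, groups)
    shared = partition.taxa(SHARED_ALL)
    assert truth.shared_core <= shared
    for g, taxa in truth.group_specific.items():
        assert taxa <= partition.taxa(UNIQUE)
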