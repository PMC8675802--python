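"""Expression I/O, MAXMIN normalization, rank-sum ranking, gene selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from rbmgrn import (
    ExpressionMatrix,
    SyntheticSpec,
    generate,
    maxmin_normalize,
    read_expression_table,
    read_geo_soft_gds,
    select_genes,
    wilcoxon_rank_genes,
    write_expression_table,
)
from rbmgrn.expression import ExpressionFormatError

# ---------------------------------------------------------------- delimited IO


def _write_table1(tmp_path, tables, phenotype_row=None):
    lines = ["gene_id\t" + "\t".join(tables["table1"].columns)]
    if phenotype_row:
        lines.append("#group\t" + "\t".join(phenotype_row))
    for gene, row in tables["table1"].iterrows():
        lines.append(gene + "\t" + "\t".join(str(v) for v in row))
    path = tmp_path / "table1.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_read_table_values_and_ids(tmp_path, tables):
    path = _write_table1(tmp_path, tables)
    matrix = read_expression_table(path)
    assert matrix.gene_ids == [f"Gene{i}" for i in range(1, 6)]
    assert matrix.sample_ids == [f"Sample{i}" for i in range(1, 7)]
    assert matrix.data.loc["Gene1", "Sample1"] == pytest.approx(5.27055)
    assert matrix.data.loc["Gene2", "Sample3"] == pytest.approx(8.54414)


def test_read_table_phenotype_row(tmp_path, tables):
    labels = ["normal"] * 3 + ["diseased"] * 3
    path = _write_table1(tmp_path, tables, phenotype_row=labels)
    matrix = read_expression_table(path)
    assert matrix.samples_in_group("normal") == ["Sample1", "Sample2", "Sample3"]
    assert matrix.phenotype["Sample6"] == "diseased"


@pytest.mark.parametrize(
    "content, match",
    [
        ("", "empty"),
        ("g\ts1\ts2\nA\t1\t2\nA\t3\t4\n", "duplicate gene id"),
        ("g\ts1\ts2\nA\t1\tx\n", "non-numeric"),
        ("g\ts1\ts2\nA\t1\n", "expected 2"),
    ],
)
def test_read_table_format_errors(tmp_path, content, match):
    path = tmp_path / "bad.tsv"
    path.write_text(content)
    with pytest.raises(ExpressionFormatError, match=match):
        read_expression_table(path)


def test_error_names_offending_cell(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("g\ts1\ts2\nGeneA\t1\toops\n")
    with pytest.raises(ExpressionFormatError, match="GeneA.*s2"):
        read_expression_table(path)


def test_write_read_round_trip_is_identity(tmp_path):
    matrix = generate(SyntheticSpec(n_genes=7, n_samples=9, seed=11))
    path = write_expression_table(matrix, tmp_path / "m.tsv")
    back = read_expression_table(path)
    assert back.gene_ids == matrix.gene_ids
    assert back.sample_ids == matrix.sample_ids
    assert np.array_equal(back.values, matrix.values)  # bit-for-bit


def test_round_trip_preserves_phenotype(tmp_path):
    df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["A", "B"], columns=["s1", "s2"])
    matrix = ExpressionMatrix(df, {"s1": "normal", "s2": "diseased"})
    back = read_expression_table(write_expression_table(matrix, tmp_path / "p.tsv"))
    assert back.phenotype == matrix.phenotype


# ------------------------------------------------------------------ SOFT files

SOFT_FIXTURE = """\
^DATASET = GDS0000
!dataset_title = synthetic three-gene example
#ID_REF = probe id
#IDENTIFIER = gene symbol
^SUBSET = GDS0000_1
!subset_description = normal
!subset_sample_id = GSM1,GSM2
^SUBSET = GDS0000_2
!subset_description = diseased
!subset_sample_id = GSM3,GSM4
!dataset_table_begin
ID_REF\tIDENTIFIER\tGSM1\tGSM2\tGSM3\tGSM4
P1\tAKT2\t5.1\t5.3\t6.0\t6.2
P2\tFOS\t7.2\t7.1\t7.4\t7.3
P3\t\t4.0\t4.1\t4.2\t4.3
!dataset_table_end
"""


def test_soft_parser_matrix_and_subsets(tmp_path):
    path = tmp_path / "toy.soft"
    path.write_text(SOFT_FIXTURE)
    matrix = read_geo_soft_gds(path)
    assert matrix.gene_ids == ["AKT2", "FOS", "P3"]  # blank IDENTIFIER -> ID_REF
    assert matrix.sample_ids == ["GSM1", "GSM2", "GSM3", "GSM4"]
    assert matrix.samples_in_group("normal") == ["GSM1", "GSM2"]
    assert matrix.samples_in_group("diseased") == ["GSM3", "GSM4"]


def test_soft_parser_drops_non_numeric_rows(tmp_path):
    path = tmp_path / "null.soft"
    path.write_text(SOFT_FIXTURE.replace("7.4", "null"))
    matrix = read_geo_soft_gds(path)
    assert matrix.gene_ids == ["AKT2", "P3"]
    assert matrix.n_samples == 4


def test_soft_parser_agrees_with_naive_line_parse(tmp_path):
    path = tmp_path / "toy.soft"
    path.write_text(SOFT_FIXTURE)
    matrix = read_geo_soft_gds(path)
    # independent line-by-line parse of the table block
    lines = SOFT_FIXTURE.splitlines()
    start = lines.index("!dataset_table_begin") + 2
    expected = [
        [float(v) for v in ln.split("\t")[2:]]
        for ln in lines[start : start + 3]
    ]
    assert np.allclose(matrix.values, expected)


def test_soft_parser_requires_table(tmp_path):
    path = tmp_path / "empty.soft"
    path.write_text("^DATASET = GDS0000\n!dataset_title = nothing\n")
    with pytest.raises(ExpressionFormatError, match="table"):
        read_geo_soft_gds(path)


def test_soft_parser_ignores_unknown_subset_sample(tmp_path, caplog):
    path = tmp_path / "toy.soft"
    path.write_text(SOFT_FIXTURE.replace("GSM3,GSM4", "GSM3,GSM9"))
    matrix = read_geo_soft_gds(path)
    assert "GSM9" not in matrix.phenotype
    assert matrix.phenotype["GSM3"] == "diseased"


# -------------------------------------------------------------- normalization


def test_maxmin_matches_printed_gene1_row(tables):
    matrix = ExpressionMatrix(tables["table1"].copy())
    normalized = maxmin_normalize(matrix)
    expected = [0.6355, 0, 0.4381, 0.5725, 1, 0.1982]
    assert np.allclose(normalized.data.loc["Gene1"], expected, atol=1e-4)


def test_maxmin_constant_row_maps_to_zeros():
    df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["A", "B"],
                      columns=["s1", "s2", "s3"])
    normalized = maxmin_normalize(ExpressionMatrix(df))
    assert np.array_equal(normalized.data.loc["A"], [0, 0, 0])
    assert np.array_equal(normalized.data.loc["B"], [0, 0.5, 1])


def test_maxmin_fixed_point_on_unit_row():
    df = pd.DataFrame([[0.0, 1.0]], index=["A"], columns=["s1", "s2"])
    assert np.array_equal(
        maxmin_normalize(ExpressionMatrix(df)).values, [[0.0, 1.0]]
    )


@settings(deadline=None, max_examples=50)
@given(
    arrays(
        np.float64,
        st.tuples(st.integers(1, 5), st.integers(2, 8)),
        elements=st.floats(-100, 100, allow_nan=False, width=64),
    )
)
def test_maxmin_range_idempotence_and_order(values):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    once = maxmin_normalize(ExpressionMatrix(df))
    for raw_row, norm_row in zip(values, once.values):
        if np.ptp(raw_row) > 0:
            assert norm_row.min() == 0.0 and norm_row.max() == 1.0
            # order statistics preserved: rescaling is monotone non-decreasing
            order = np.argsort(raw_row, kind="stable")
            assert (np.diff(norm_row[order]) >= 0).all()
        else:
            assert np.array_equal(norm_row, np.zeros_like(norm_row))
    twice = maxmin_normalize(once)
    assert np.allclose(twice.values, once.values, atol=1e-15)


# ------------------------------------------------------------------- rank test


def _exact_two_sided_p(a, b):
    """Exhaustive permutation two-sided p for the rank-sum statistic."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mu = n1 * (len(pooled) + 1) / 2
    observed = abs(ranks[: len(a)].sum() - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= observed - 1e-9:
            hits += 1
    return hits / total


#: documented worst-case gap between the tie-corrected normal approximation
#: (no continuity correction) and the exact permutation p at total n <= 8
#: (exhaustive over all rank-sum values and group splits: 0.237 at 2 vs 3)
NORMAL_APPROX_BOUND = 0.24


def _two_group_matrix(rows, labels):
    df = pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(len(labels))],
    )
    return ExpressionMatrix(df, {f"s{j}": lab for j, lab in enumerate(labels)})


def test_ranksum_agrees_with_exhaustive_enumeration():
    separated = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    flat = [2.0, 4.0, 6.0, 1.0, 3.0, 5.0]
    matrix = _two_group_matrix([separated, flat], ["a"] * 3 + ["b"] * 3)
    ranked = wilcoxon_rank_genes(matrix, "a", "b")
    by_id = {r.gene_id: r for r in ranked}
    exact = _exact_two_sided_p(np.array(separated[:3]), np.array(separated[3:]))
    assert exact == pytest.approx(0.1)  # 2 of the 20 assignments are as extreme
    assert abs(by_id["g0"].p_value - exact) <= NORMAL_APPROX_BOUND
    assert by_id["g0"].rank < by_id["g1"].rank  # separated gene outranks flat one


def test_ranksum_random_small_samples_against_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 9 - n1))
        values = rng.normal(size=n1 + n2)  # continuous, no ties
        matrix = _two_group_matrix([values], ["a"] * n1 + ["b"] * n2)
        (ranked,) = wilcoxon_rank_genes(matrix, "a", "b")
        exact = _exact_two_sided_p(values[:n1], values[n1:])
        assert abs(ranked.p_value - exact) <= NORMAL_APPROX_BOUND


def test_ranksum_fully_tied_gene_is_null():
    matrix = _two_group_matrix([[3.0] * 6], ["a"] * 3 + ["b"] * 3)
    (ranked,) = wilcoxon_rank_genes(matrix, "a", "b")
    assert ranked.statistic == 0.0
    assert ranked.p_value == 1.0


def test_ranksum_group_swap_negates_z_keeps_p():
    rows = [[1.0, 2.0, 3.0, 7.0, 8.0, 9.0], [5.0, 1.0, 9.0, 2.0, 8.0, 3.0]]
    matrix = _two_group_matrix(rows, ["a"] * 3 + ["b"] * 3)
    forward = wilcoxon_rank_genes(matrix, "a", "b")
    backward = wilcoxon_rank_genes(matrix, "b", "a")
    fwd = {r.gene_id: r for r in forward}
    bwd = {r.gene_id: r for r in backward}
    for gene in fwd:
        assert fwd[gene].statistic == pytest.approx(-bwd[gene].statistic)
        assert fwd[gene].p_value == pytest.approx(bwd[gene].p_value)


def test_ranksum_ranks_are_a_permutation(tables):
    matrix = ExpressionMatrix(
        tables["table1"].copy(),
    )
    matrix.phenotype.update(
        {s: ("a" if i < 3 else "b") for i, s in enumerate(matrix.sample_ids)}
    )
    ranked = wilcoxon_rank_genes(matrix, "a", "b")
    assert sorted(r.rank for r in ranked) == list(range(1, 6))
    assert all(0 <= r.p_value <= 1 for r in ranked)


def test_ranksum_unknown_label_raises(raw_matrix):
    with pytest.raises(ValueError, match="no samples"):
        wilcoxon_rank_genes(raw_matrix, "nope", "also_nope")


# ------------------------------------------------------------------- selection


def test_select_identity(raw_matrix):
    out = select_genes(raw_matrix, raw_matrix.gene_ids)
    assert out.equals(raw_matrix)


def test_select_reorders_rows(raw_matrix, tables):
    out = select_genes(raw_matrix, ["Gene3", "Gene1"])
    assert out.gene_ids == ["Gene3", "Gene1"]
    assert np.array_equal(out.values[0], tables["table1"].loc["Gene3"].to_numpy())
    assert np.array_equal(out.values[1], tables["table1"].loc["Gene1"].to_numpy())


def test_select_missing_id_lists_missing(raw_matrix):
    with pytest.raises(ValueError, match="Gene9"):
        select_genes(raw_matrix, ["Gene1", "Gene9"])


def test_select_on_gene_set_intersection(raw_matrix):
    other = generate(SyntheticSpec(n_genes=4, n_samples=6, seed=0))
    renamed = ExpressionMatrix(
        other.data.set_axis(["Gene2", "Gene4", "GeneX", "GeneY"], axis=0)
    )
    common = sorted(set(raw_matrix.gene_ids) & set(renamed.gene_ids))
    assert common == ["Gene2", "Gene4"]
    assert select_genes(raw_matrix, common).gene_ids == common
    assert select_genes(renamed, common).gene_ids == common
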