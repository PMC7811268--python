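"""Composition statistics: totals, mol%, fold changes, DBI, group tests."""
import numpy as np
import pandas as pd
import pytest

from conftest import matrix_from_amounts
from lipidregnet.errors import (
    DegenerateScope,
    EmptyInput,
    InputError,
    InsufficientReplicates,
    UnresolvedChains,
)
from lipidregnet.lipidome import (
    LipidomeMatrix,
    class_totals,
    dbi,
    dbi_by_class,
    dbi_percent_change,
    fa_composition,
    fold_change,
    kruskal_wallis,
    kruskal_wallis_table,
    mol_percent,
)

# ---------------------------------------------------------------------------
# matrix construction


def test_empty_matrix_rejected():
    with pytest.raises(EmptyInput):
        LipidomeMatrix.from_long(
            pd.DataFrame(columns=["species", "condition", "replicate", "amount"])
        )


def test_duplicate_species_rejected():
    with pytest.raises(InputError):
        matrix_from_amounts({
            "TAG 52:3": {("NT", 1): 1.0},
            "TAG(52:3)": {("NT", 1): 2.0},  # same species, other dialect
        })


def test_wide_and_long_roundtrip(tmp_path, tiny_matrix):
    path = tmp_path / "wide.tsv"
    flat = tiny_matrix.amounts.copy()
    flat.columns = [f"{c}_{r}" for c, r in flat.columns]
    flat.rename_axis("species").to_csv(path, sep="\t")
    again = LipidomeMatrix.read_wide(path)
    pd.testing.assert_frame_equal(
        again.amounts.sort_index(axis=1),
        tiny_matrix.amounts.sort_index(axis=1).set_axis(
            again.amounts.sort_index(axis=1).columns, axis=1),
        check_names=False,
    )


# ---------------------------------------------------------------------------
# class totals


def test_class_totals_identity_and_addition():
    m = matrix_from_amounts({
        "TAG 52:3": {("NT", 1): 4.0},
        "PC 34:1": {("NT", 1): 1.0},
        "PC 36:2": {("NT", 1): 2.0},
        "PI 34:1": {("NT", 1): 3.0},
    })
    totals = class_totals(m)[("NT", 1)]
    assert totals["TAG"] == 4.0
    assert totals["PC"] == 3.0
    assert totals["PI"] == 3.0


def test_class_totals_conserve_mass(default_sim):
    matrix, _ = default_sim
    totals = class_totals(matrix)
    np.testing.assert_allclose(
        totals.sum(axis=0).to_numpy(),
        matrix.amounts.sum(axis=0).to_numpy(),
        rtol=1e-12,
    )


# ---------------------------------------------------------------------------
# mol%


def test_mol_percent_single_member_is_100():
    m = matrix_from_amounts({"TAG 52:3": {("NT", 1): 0.7}})
    out = mol_percent(m, "total_glycerolipids", "class")
    assert out["mol_percent"].iloc[0] == pytest.approx(100.0)


def test_mol_percent_forced_arithmetic():
    m = matrix_from_amounts({
        "PC 34:1": {("NT", 1): 1.0},
        "PC 36:2": {("NT", 1): 1.0},
        "PC 36:4": {("NT", 1): 2.0},
    })
    out = mol_percent(m, "total_glycerolipids", "species")
    got = dict(zip(out["unit"], out["mol_percent"]))
    assert got == {"PC 34:1": pytest.approx(25.0),
                   "PC 36:2": pytest.approx(25.0),
                   "PC 36:4": pytest.approx(50.0)}


def test_mol_percent_scope_membership(tiny_matrix):
    mem = mol_percent(tiny_matrix, "membrane_lipids_only", "class")
    assert set(mem["unit"]) == {"PC", "MGDG"}  # TAG (neutral) excluded
    phos = mol_percent(tiny_matrix, "phospholipids_only", "class")
    assert set(phos["unit"]) == {"PC"}


def test_mol_percent_degenerate_scope():
    m = matrix_from_amounts({"TAG 52:3": {("NT", 1): 1.0}})
    with pytest.raises(DegenerateScope):
        mol_percent(m, "membrane_lipids_only", "class")


def test_mol_percent_scale_invariance(tiny_matrix):
    scaled = LipidomeMatrix(list(tiny_matrix.species),
                            tiny_matrix.amounts * 37.5)
    for scope in ("total_glycerolipids", "membrane_lipids_only"):
        a = mol_percent(tiny_matrix, scope, "class")["mol_percent"]
        b = mol_percent(scaled, scope, "class")["mol_percent"]
        np.testing.assert_allclose(a, b, rtol=1e-12)


# ---------------------------------------------------------------------------
# fold change


def test_fold_change_identity(tiny_matrix):
    fc = fold_change(tiny_matrix, "NT", "NT", level="class")
    np.testing.assert_allclose(fc.to_numpy(), 1.0)


def test_fold_change_forced_arithmetic(tiny_matrix):
    fc = fold_change(tiny_matrix, "LT", "NT", level="class")
    assert fc["TAG"] == pytest.approx(2.3)  # 4.6 / 2.0
    assert fc["PC"] == pytest.approx(1.0)   # (0.5 + 1.5) vs (1 + 1)


def test_fold_change_zero_control_is_missing():
    m = matrix_from_amounts({
        "TAG 52:3": {("NT", 1): 0.0, ("LT", 1): 1.0},
        "PC 34:1": {("NT", 1): 1.0, ("LT", 1): 1.0},
    })
    fc = fold_change(m, "LT", "NT", level="class")
    assert np.isnan(fc["TAG"])
    assert np.isfinite(fc["PC"])


def test_fold_change_missing_condition(tiny_matrix):
    with pytest.raises(InputError):
        fold_change(tiny_matrix, "HT", "NT")


# ---------------------------------------------------------------------------
# DBI


def test_dbi_saturated_limit():
    m = matrix_from_amounts({
        "PC 34:0": {("NT", 1): 1.0},
        "PE 36:0": {("NT", 1): 2.0},
    })
    assert dbi(m, "membrane_lipids_only")["NT"] == pytest.approx(0.0)


def test_dbi_convexity_midpoint():
    m = matrix_from_amounts({
        "PC 34:2": {("NT", 1): 5.0},
        "PC 36:4": {("NT", 1): 5.0},
    })
    assert dbi(m, "membrane_lipids_only")["NT"] == pytest.approx(3.0)


def test_dbi_percent_change_forced():
    # class DBI 2.0 at NT -> 3.0 at LT is +50%
    m = matrix_from_amounts({
        "PC 34:2": {("NT", 1): 1.0, ("LT", 1): 0.5},
        "PC 36:4": {("NT", 1): 0.0, ("LT", 1): 0.5},
    })
    change = dbi_percent_change(m, "LT", "NT")
    assert change["PC"] == pytest.approx(50.0)
    unchanged = dbi_percent_change(m, "NT", "NT")
    assert unchanged["PC"] == pytest.approx(0.0)


def test_dbi_by_class_zero_total_is_nan():
    m = matrix_from_amounts({
        "PC 34:2": {("NT", 1): 1.0, ("LT", 1): 0.0},
        "TAG 52:3": {("NT", 1): 1.0, ("LT", 1): 1.0},
    })
    table = dbi_by_class(m)
    assert np.isnan(table.loc["PC", "LT"])
    assert table.loc["PC", "NT"] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# fatty-acid composition


def test_fa_single_species_single_fa():
    m = matrix_from_amounts({"MGDG 36:6(18:3/18:3)": {("NT", 1): 2.0}})
    out = fa_composition(m, "MGDG")
    assert out["fatty_acid"].unique().tolist() == ["18:3"]
    assert out["mol_percent"].iloc[0] == pytest.approx(100.0)


def test_fa_chain_counting():
    # A(16:0/18:1) at 1 and B(18:1/18:1) at 1 -> 16:0 25%, 18:1 75%
    m = matrix_from_amounts({
        "PC 34:1(16:0/18:1)": {("NT", 1): 1.0},
        "PC 36:2(18:1/18:1)": {("NT", 1): 1.0},
    })
    out = fa_composition(m, "PC")
    got = dict(zip(out["fatty_acid"], out["mol_percent"]))
    assert got["16:0"] == pytest.approx(25.0)
    assert got["18:1"] == pytest.approx(75.0)


def test_fa_requires_resolved_chains(tiny_matrix):
    with pytest.raises(UnresolvedChains):
        fa_composition(tiny_matrix, "TAG")


def test_fa_sums_to_100_per_condition():
    m = matrix_from_amounts({
        "MGDG 36:6(18:3/18:3)": {("NT", 1): 2.0, ("LT", 1): 5.0},
        "MGDG 34:3(16:0/18:3)": {("NT", 1): 3.0, ("LT", 1): 1.0},
    })
    out = fa_composition(m, "MGDG")
    sums = out.groupby("condition")["mol_percent"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 100.0, rtol=1e-12)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def test_kw_all_equal_exact():
    res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]], exact=True)
    assert res.h == 0.0
    assert res.p_value == 1.0


def test_kw_insufficient_replicates():
    with pytest.raises(InsufficientReplicates):
        kruskal_wallis([[1.0], [2.0, 3.0]])
    with pytest.raises(InsufficientReplicates):
        kruskal_wallis([[1.0, 2.0]])


def test_kw_matches_scipy_chi2_mode(rng):
    from scipy.stats import kruskal

    for _ in range(20):
        groups = [rng.normal(size=4) for _ in range(3)]
        mine = kruskal_wallis(groups)
        h, p = kruskal(*groups)
        assert mine.h == pytest.approx(h, rel=1e-12)
        assert mine.p_value == pytest.approx(p, rel=1e-12)


def test_kw_chi2_tracks_exact_p(rng):
    """The chi-square approximation follows the exact permutation p closely
    at the replicate counts of a 3-condition, 4-replicate design (bound
    derived from a full-enumeration study of random datasets)."""
    worst = 0.0
    for _ in range(25):
        groups = [np.round(rng.normal(size=4), 1) for _ in range(3)]
        approx = kruskal_wallis(groups, exact=False)
        exact = kruskal_wallis(groups, exact=True)
        assert exact.h == pytest.approx(approx.h, rel=1e-12)
        worst = max(worst, abs(exact.p_value - approx.p_value))
    assert worst < 0.1


def test_kw_table_on_tiny(tiny_matrix):
    table = kruskal_wallis_table(tiny_matrix, level="class", exact=True)
    assert set(table["unit"]) == {"TAG", "PC", "MGDG"}
    assert table["p_value"].between(0, 1).all()
    # MGDG identical across conditions -> no separation
    row = table.set_index("unit").loc["MGDG"]
    assert row["h"] == pytest.approx(0.0)
    assert row["p_value"] == pytest.approx(1.0)
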