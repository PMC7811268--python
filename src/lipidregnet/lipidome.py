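"""Lipidome composition statistics.

Works on a species x sample matrix of absolute amounts (nmol per mg dry
weight) carrying condition/replicate metadata, as produced by targeted
LC-MS glycerolipidomics after upstream quantification. The statistics here
are the standard descriptive layer of a temperature-stress lipidomics study:

* per-class totals and mol%% under an explicit denominator *scope*
  (all glycerolipids, one class, phospholipids only, or membrane lipids only
  -- membrane meaning everything except the neutral TAG/DAG/MAG fraction);
* fold changes of replicate-mean amounts between conditions;
* the double-bond index (DBI), the mol-fraction-weighted mean number of C=C
  double bonds per molecule within a scope -- the usual bulk unsaturation
  measure for membranes;
* per-fatty-acid composition of a class from resolved acyl chains;
* the Kruskal-Wallis rank test between condition groups, with an exact
  enumeration mode for the tiny replicate counts (n = 4 per group) typical
  of lipidomics designs, where the chi-square approximation is rough.

Replicate aggregation is the arithmetic mean per condition, taken before any
ratio or mol%% computation; SDs are carried alongside.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateScope,
    EmptyInput,
    InputError,
    InsufficientReplicates,
    UnresolvedChains,
)
from .nomenclature import LipidSpecies, parse_species

__all__ = [
    "SCOPES",
    "LipidomeMatrix",
    "GroupTestResult",
    "class_totals",
    "mol_percent",
    "fold_change",
    "dbi",
    "dbi_by_class",
    "dbi_percent_change",
    "fa_composition",
    "kruskal_wallis",
    "kruskal_wallis_table",
]

#: Denominator scopes for mol% and DBI.
SCOPES = ("total_glycerolipids", "within_class", "phospholipids_only",
          "membrane_lipids_only")

#: Preferred display order for the three culture temperatures.
_CONDITION_ORDER = ("LT", "NT", "HT")


class LipidomeMatrix:
    """Species x sample amounts with condition/replicate metadata.

    Parameters
    ----------
    species:
        Parsed :class:`~lipidregnet.nomenclature.LipidSpecies`, one per row.
    amounts:
        DataFrame indexed by the canonical species names, columns a
        two-level MultiIndex ``(condition, replicate)``; nonnegative values
        in nmol per mg dry weight. Zeros mean "below detection".
    """

    def __init__(self, species: Sequence[LipidSpecies], amounts: pd.DataFrame):
        if len(species) == 0 or amounts.empty:
            raise EmptyInput("lipidome matrix has no species")
        names = [sp.canonical() for sp in species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate species: {dupes[:5]}")
        if list(amounts.index) != names:
            raise InputError("amounts index must match species canonical names")
        if amounts.columns.nlevels != 2:
            raise InputError("amounts columns must be (condition, replicate)")
        if (amounts.to_numpy() < 0).any():
            raise InputError("negative amounts")
        self.species: tuple[LipidSpecies, ...] = tuple(species)
        self.amounts: pd.DataFrame = amounts.astype(float)
        self.amounts.columns = self.amounts.columns.set_names(
            ["condition", "replicate"]
        )

    # -- metadata ---------------------------------------------------------

    @property
    def species_meta(self) -> pd.DataFrame:
        """Per-species class / totals / category table."""
        return pd.DataFrame(
            {
                "lipid_class": [sp.lipid_class for sp in self.species],
                "total_carbons": [sp.total_carbons for sp in self.species],
                "total_double_bonds": [sp.total_double_bonds for sp in self.species],
                "category": [sp.category for sp in self.species],
            },
            index=self.amounts.index,
        )

    @property
    def conditions(self) -> tuple[str, ...]:
        present = list(dict.fromkeys(self.amounts.columns.get_level_values(0)))
        ordered = [c for c in _CONDITION_ORDER if c in present]
        return tuple(ordered + [c for c in present if c not in ordered])

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(sp.lipid_class for sp in self.species))

    @property
    def detected(self) -> pd.DataFrame:
        """Per-cell detection flag (amount above zero)."""
        return self.amounts > 0

    # -- aggregation ------------------------------------------------------

    def condition_means(self, level: str = "species") -> pd.DataFrame:
        """Replicate-mean amounts per condition, at species or class level."""
        base = self.amounts if level == "species" else class_totals(self)
        out = base.T.groupby(level="condition").mean().T
        return out[list(self.conditions)]

    def condition_sd(self, level: str = "species") -> pd.DataFrame:
        base = self.amounts if level == "species" else class_totals(self)
        out = base.T.groupby(level="condition").std(ddof=1).T
        return out[list(self.conditions)]

    # -- construction / IO ------------------------------------------------

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "LipidomeMatrix":
        """Build from a long table with columns species, condition,
        replicate, amount."""
        required = {"species", "condition", "replicate", "amount"}
        missing = required - set(table.columns)
        if missing:
            raise InputError(f"long table missing columns {sorted(missing)}")
        if table.empty:
            raise EmptyInput("empty lipidome table")
        parsed: dict[str, LipidSpecies] = {}
        for raw in dict.fromkeys(table["species"]):
            try:
                sp = parse_species(str(raw))
            except Exception as exc:
                raise InputError(f"species {raw!r}: {exc}") from exc
            key = sp.canonical()
            if key in parsed:
                raise InputError(
                    f"species {raw!r} duplicates {parsed[key].raw_name!r} "
                    f"(both parse to {key})"
                )
            parsed[key] = sp
        canon = {sp.raw_name: k for k, sp in parsed.items()}
        work = table.assign(_name=table["species"].astype(str).map(canon))
        wide = work.pivot_table(
            index="_name", columns=["condition", "replicate"], values="amount",
            aggfunc="sum", fill_value=0.0,
        )
        wide = wide.reindex(list(parsed))
        return cls(list(parsed.values()), wide)

    @classmethod
    def read_long(cls, path: str | Path) -> "LipidomeMatrix":
        """Read a long-format TSV/CSV (columns species, condition, replicate,
        amount; ``#`` comments allowed)."""
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            table = pd.read_csv(path, sep=sep, comment="#")
        except Exception as exc:
            raise InputError(f"cannot read {path}: {exc}") from exc
        return cls.from_long(table)

    @classmethod
    def read_wide(cls, path: str | Path) -> "LipidomeMatrix":
        """Read a wide table: species rows x sample columns named like
        ``LT_1``; first column holds species names. TSV/CSV/xlsx."""
        path = Path(path)
        try:
            if path.suffix.lower() in (".xlsx", ".xls"):
                table = pd.read_excel(path, index_col=0)
            else:
                sep = "," if path.suffix.lower() == ".csv" else "\t"
                table = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        except Exception as exc:
            raise InputError(f"cannot read {path}: {exc}") from exc
        long = (
            table.reset_index(names="species")
            .melt(id_vars="species", var_name="sample", value_name="amount")
        )
        split = long["sample"].astype(str).str.rsplit("_", n=1, expand=True)
        if split.shape[1] != 2 or split.isna().any().any():
            raise InputError("wide columns must be named '<condition>_<replicate>'")
        long["condition"] = split[0]
        long["replicate"] = split[1]
        return cls.from_long(long[["species", "condition", "replicate", "amount"]])

    def to_long(self) -> pd.DataFrame:
        out = (
            self.amounts.stack(["condition", "replicate"], future_stack=True)
            .rename("amount")
            .reset_index()
            .rename(columns={"_name": "species", "level_0": "species"})
        )
        out.columns = ["species", "condition", "replicate", "amount"]
        return out


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis outcome: H statistic, p-value, labels, p-value mode."""

    h: float
    p_value: float
    groups: tuple[str, ...]
    method: str  # "chi2" or "exact"


# ---------------------------------------------------------------------------
# scopes


def _scope_mask(matrix: LipidomeMatrix, scope: str) -> np.ndarray:
    meta = matrix.species_meta
    if scope == "total_glycerolipids":
        return np.ones(len(meta), dtype=bool)
    if scope == "membrane_lipids_only":
        return (meta["category"] != "neutral").to_numpy()
    if scope == "phospholipids_only":
        return (meta["category"] == "phospholipid").to_numpy()
    raise ValueError(f"unknown scope {scope!r} (within_class is per-class only)")


# ---------------------------------------------------------------------------
# totals, mol%, fold changes


def class_totals(matrix: LipidomeMatrix) -> pd.DataFrame:
    """Per-class, per-sample totals (nmol per mg DW).

    The sum over classes equals the sum over species in every sample
    (mass bookkeeping, no species dropped).
    """
    by_class = matrix.amounts.groupby(
        matrix.species_meta["lipid_class"], sort=False
    ).sum()
    by_class.index.name = "lipid_class"
    return by_class


def mol_percent(
    matrix: LipidomeMatrix,
    scope: str = "total_glycerolipids",
    level: str = "class",
) -> pd.DataFrame:
    """Mol%% of classes or species under a denominator scope.

    mol%% = 100 x (member replicate-mean amount) / (scope total of replicate
    means), per condition. With ``scope='within_class'`` (species level only)
    each species is expressed relative to its own class total.

    Returns a tidy frame: unit, lipid_class, condition, mean_amount,
    sd_amount, mol_percent, scope, level.
    """
    if level not in ("class", "species"):
        raise ValueError("level must be 'class' or 'species'")
    if scope == "within_class" and level != "species":
        raise ValueError("within_class scope applies at species level")

    meta = matrix.species_meta
    means = matrix.condition_means(level)
    sds = matrix.condition_sd(level)

    if scope == "within_class":
        denom = means.groupby(meta["lipid_class"], sort=False).transform("sum")
        if (denom.to_numpy() == 0).any():
            bad = denom.index[(denom == 0).any(axis=1)][:5].tolist()
            raise DegenerateScope(f"zero class total behind species {bad}")
        member = means
    else:
        mask = _scope_mask(matrix, scope)
        if not mask.any():
            raise DegenerateScope(f"no species in scope {scope}")
        if level == "species":
            member = means.loc[mask]
            sds = sds.loc[mask]
            denom_row = member.sum(axis=0)
        else:
            scoped_classes = meta.loc[mask, "lipid_class"].unique()
            member = means.loc[means.index.isin(scoped_classes)]
            sds = sds.loc[member.index]
            denom_row = member.sum(axis=0)
        if (denom_row == 0).any():
            bad = denom_row.index[denom_row == 0].tolist()
            raise DegenerateScope(f"scope {scope} total is zero in {bad}")
        denom = pd.DataFrame(
            np.broadcast_to(denom_row.to_numpy(), member.shape),
            index=member.index, columns=member.columns,
        )

    pct = 100.0 * member / denom
    unit_class = (
        meta["lipid_class"].reindex(member.index)
        if level == "species"
        else pd.Series(member.index, index=member.index)
    )
    rows = []
    for cond in member.columns:
        rows.append(pd.DataFrame({
            "unit": member.index,
            "lipid_class": unit_class.to_numpy(),
            "condition": cond,
            "mean_amount": member[cond].to_numpy(),
            "sd_amount": sds[cond].reindex(member.index).to_numpy(),
            "mol_percent": pct[cond].to_numpy(),
        }))
    out = pd.concat(rows, ignore_index=True)
    out["scope"] = scope
    out["level"] = level
    return out


def fold_change(
    matrix: LipidomeMatrix,
    treatment: str,
    control: str,
    level: str = "class",
) -> pd.Series:
    """Per-unit ratio of replicate-mean amounts, treatment over control.

    Units whose control mean is zero get NaN (undefined, reported as
    missing rather than infinity).
    """
    means = matrix.condition_means(level)
    for cond in (treatment, control):
        if cond not in means.columns:
            raise InputError(f"condition {cond!r} not present")
    num = means[treatment]
    den = means[control]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio[den == 0] = np.nan
    ratio.name = f"fold_{treatment}_vs_{control}"
    return ratio


# ---------------------------------------------------------------------------
# double-bond index


def dbi(matrix: LipidomeMatrix, scope: str = "membrane_lipids_only") -> pd.Series:
    """Double-bond index per condition under a scope.

    DBI = sum over scope species of (mol fraction within scope, from
    replicate means) x (total double bonds of the species). Zero when every
    species in scope is fully saturated.
    """
    mask = _scope_mask(matrix, scope)
    if not mask.any():
        raise DegenerateScope(f"no species in scope {scope}")
    means = matrix.condition_means("species").loc[mask]
    totals = means.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise DegenerateScope(f"scope {scope} total is zero in {bad}")
    db = matrix.species_meta.loc[means.index, "total_double_bonds"]
    out = means.mul(db, axis=0).sum(axis=0) / totals
    out.name = f"dbi[{scope}]"
    return out


def dbi_by_class(matrix: LipidomeMatrix) -> pd.DataFrame:
    """Within-class DBI, classes x conditions (NaN where a class total is 0)."""
    means = matrix.condition_means("species")
    meta = matrix.species_meta
    weighted = means.mul(meta["total_double_bonds"], axis=0)
    num = weighted.groupby(meta["lipid_class"], sort=False).sum()
    den = means.groupby(meta["lipid_class"], sort=False).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    out.index.name = "lipid_class"
    return out


def dbi_percent_change(
    matrix: LipidomeMatrix, treatment: str, control: str
) -> pd.Series:
    """Per-class relative DBI change, 100 x (DBI_t - DBI_c) / DBI_c.

    Classes with a zero (or undefined) control DBI come back as NaN.
    """
    table = dbi_by_class(matrix)
    for cond in (treatment, control):
        if cond not in table.columns:
            raise InputError(f"condition {cond!r} not present")
    ctrl = table[control]
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (table[treatment] - ctrl) / ctrl
    change[(ctrl == 0) | ctrl.isna()] = np.nan
    change.name = f"dbi_pct_change_{treatment}_vs_{control}"
    return change


# ---------------------------------------------------------------------------
# fatty-acid composition


def fa_composition(matrix: LipidomeMatrix, lipid_class: str) -> pd.DataFrame:
    """Fatty-acid mol%% table for one class, from resolved acyl chains.

    Each chain occurrence contributes its species' replicate-mean amount once,
    so a diacyl species with identical chains contributes twice to that FA.
    Percentages sum to 100 per condition.
    """
    members = [sp for sp in matrix.species if sp.lipid_class == lipid_class]
    if not members:
        raise DegenerateScope(f"no species of class {lipid_class!r}")
    lacking = [sp.canonical() for sp in members if not sp.chains]
    if lacking:
        raise UnresolvedChains(
            f"species without resolved chains in {lipid_class}: {lacking[:5]}"
        )
    means = matrix.condition_means("species")
    buckets: dict[str, pd.Series] = {}
    for sp in members:
        amount = means.loc[sp.canonical()]
        for chain in sp.chains:
            fa = str(chain)
            buckets[fa] = buckets.get(fa, 0.0) + amount
    table = pd.DataFrame(buckets).T.sort_index()
    totals = table.sum(axis=0)
    if (totals == 0).any():
        raise DegenerateScope(f"class {lipid_class} total is zero")
    pct = 100.0 * table / totals
    out = (
        pct.rename_axis("fatty_acid")
        .reset_index()
        .melt(id_vars="fatty_acid", var_name="condition", value_name="mol_percent")
    )
    out["lipid_class"] = lipid_class
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _kw_h_from_ranksums(ranksums: Iterable[float], sizes: Sequence[int],
                        n: int, tie_corr: float) -> float:
    s = sum(rs * rs / k for rs, k in zip(ranksums, sizes))
    h = 12.0 / (n * (n + 1)) * s - 3.0 * (n + 1)
    return h / tie_corr


def _tie_correction(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / float(n**3 - n)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    exact: bool = False,
) -> GroupTestResult:
    """Kruskal-Wallis rank test across two or more groups.

    H is computed on mid-ranks with the usual tie correction. The p-value
    comes from the chi-square approximation (k-1 df) by default, or, with
    ``exact=True`` and a pooled sample of at most 14 values, from full
    enumeration of every assignment of the pooled values to groups of the
    observed sizes (the exact permutation null).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientReplicates("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise InsufficientReplicates(f"group {i} has fewer than 2 values")
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(groups)))
    labels = tuple(labels)

    pooled = np.concatenate(groups)
    n = len(pooled)
    sizes = [len(g) for g in groups]
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, 1.0, labels, "exact" if exact else "chi2")

    ranks = stats.rankdata(pooled)
    tie_corr = _tie_correction(pooled)
    bounds = np.cumsum([0] + sizes)
    ranksums = [ranks[bounds[i]:bounds[i + 1]].sum() for i in range(len(sizes))]
    h = _kw_h_from_ranksums(ranksums, sizes, n, tie_corr)

    if not exact:
        return GroupTestResult(h, float(stats.chi2.sf(h, len(groups) - 1)),
                               labels, "chi2")

    if n > 14:
        raise ValueError(f"exact mode enumerates all assignments; n={n} > 14")

    total_rank = ranks.sum()
    count = 0
    total = 0

    def enumerate_assignments(remaining: tuple[int, ...], gi: int,
                              sums: list[float]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:  # last group forced
            sums.append(total_rank - sum(sums))
            hperm = _kw_h_from_ranksums(sums, sizes, n, tie_corr)
            total += 1
            if hperm >= h - 1e-12:
                count += 1
            sums.pop()
            return
        for combo in itertools.combinations(remaining, sizes[gi]):
            sums.append(sum(ranks[i] for i in combo))
            rest = tuple(i for i in remaining if i not in combo)
            enumerate_assignments(rest, gi + 1, sums)
            sums.pop()

    enumerate_assignments(tuple(range(n)), 0, [])
    return GroupTestResult(h, count / total, labels, "exact")


def kruskal_wallis_table(
    matrix: LipidomeMatrix,
    level: str = "class",
    exact: bool = False,
    detected_only: bool = False,
) -> pd.DataFrame:
    """Per-unit Kruskal-Wallis test across all conditions of the matrix.

    ``detected_only`` drops below-detection (zero) cells before testing at
    species level; units left with any group of fewer than two values are
    reported with NaN statistics rather than raising.
    """
    base = matrix.amounts if level == "species" else class_totals(matrix)
    conds = matrix.conditions
    rows = []
    for unit, row in base.iterrows():
        groups = []
        for cond in conds:
            vals = row.loc[cond].to_numpy(dtype=float)
            if detected_only and level == "species":
                vals = vals[vals > 0]
            groups.append(vals)
        if any(len(g) < 2 for g in groups):
            rows.append((unit, np.nan, np.nan, int(sum(map(len, groups)))))
            continue
        res = kruskal_wallis(groups, labels=conds, exact=exact)
        rows.append((unit, res.h, res.p_value, int(sum(map(len, groups)))))
    return pd.DataFrame(rows, columns=["unit", "h", "p_value", "n_total"])
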