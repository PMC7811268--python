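"""Expression profiles from RT-qPCR and precomputed log2FC tables.

The time-course design: cultures under low- (LT) and high-temperature (HT)
stress sampled at 48, 96 and 168 h, each compared against the normal-
temperature (NT) control at the same timepoint. Relative quantification uses
the standard Livak 2^-ddCt scheme: dCt = Ct_target - Ct_reference per
replicate, ddCt = mean dCt(treatment) - mean dCt(control), and
log2FC = -ddCt. The 0 h sample is the shared baseline of every series and is
deliberately excluded from profiles: its log2FC is 0 by construction and
would anchor every gene pair at a common point, inflating correlations
downstream.

A gene's *profile* is its log2FC vector on the fixed six-point grid
LT48, LT96, LT168, HT48, HT96, HT168. Genes missing any grid point are
flagged incomplete and excluded from network analysis rather than imputed
(mirroring how an undetected transcript simply drops out of the panel).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousRecord,
    EmptyInput,
    InputError,
    MalformedRecord,
    MissingBaseline,
    MissingReference,
)

__all__ = [
    "GRID",
    "GRID_LABELS",
    "ExpressionProfile",
    "ddct_log2fc",
    "build_profile",
    "build_profiles",
    "classify_response",
    "filter_de",
    "read_ct_table",
    "read_log2fc_wide",
    "write_profiles",
]

#: Fixed (condition, timepoint in h) grid, in documented order.
GRID: tuple[tuple[str, int], ...] = (
    ("LT", 48), ("LT", 96), ("LT", 168),
    ("HT", 48), ("HT", 96), ("HT", 168),
)

GRID_LABELS: tuple[str, ...] = tuple(f"{c}_{t}" for c, t in GRID)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene ordered log2FC vector over the fixed grid."""

    gene: str
    values: pd.Series  # indexed by GRID_LABELS, NaN where missing

    @property
    def complete(self) -> bool:
        return bool(self.values.notna().all())

    def classify(self, threshold: float = 1.0) -> pd.Series:
        return classify_response(self.values, threshold)


# ---------------------------------------------------------------------------
# ddCt


def _reference_ct(refs: pd.DataFrame, agg: str) -> pd.Series:
    grouped = refs.groupby(["condition", "timepoint", "replicate"])["ct"]
    if agg == "arithmetic":
        return grouped.mean()
    if agg == "geometric":
        return grouped.apply(lambda v: float(np.exp(np.log(v).mean())))
    raise ValueError("ref_agg must be 'arithmetic' or 'geometric'")


def ddct_log2fc(
    ct: pd.DataFrame,
    reference_genes: Sequence[str] | None = None,
    control_condition: str = "NT",
    ref_agg: str = "arithmetic",
) -> pd.DataFrame:
    """Livak relative quantification from raw Ct values.

    Parameters
    ----------
    ct:
        Long table with columns gene, condition, timepoint, replicate, ct,
        and optionally role ("target"/"reference"). Without a role column,
        ``reference_genes`` names the normalizers.
    reference_genes:
        Reference (housekeeping) gene ids; ignored when a role column exists.
    control_condition:
        Condition serving as the calibrator at each timepoint (default NT).
    ref_agg:
        How multiple reference Cts collapse per replicate: arithmetic mean of
        Ct (default) or geometric mean.

    Returns
    -------
    Tidy frame of ExpressionRecords: gene, condition, timepoint, log2fc.
    """
    required = {"gene", "condition", "timepoint", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise InputError(f"Ct table missing columns {sorted(missing)}")
    if ct.empty:
        raise EmptyInput("empty Ct table")
    if (ct["ct"] <= 0).any():
        bad = ct.loc[ct["ct"] <= 0].index[:5].tolist()
        raise InputError(f"non-positive Ct values at rows {bad}")

    if "role" in ct.columns:
        is_ref = ct["role"].astype(str).str.lower().eq("reference")
    else:
        if not reference_genes:
            raise MissingReference("no role column and no reference_genes given")
        is_ref = ct["gene"].isin(set(reference_genes))
    refs = ct.loc[is_ref]
    targets = ct.loc[~is_ref]
    if refs.empty:
        raise MissingReference("no reference observations in table")
    if targets.empty:
        raise EmptyInput("no target observations in table")

    ref_ct = _reference_ct(refs, ref_agg)
    keys = pd.MultiIndex.from_frame(targets[["condition", "timepoint", "replicate"]])
    matched = ref_ct.reindex(keys)
    if matched.isna().any():
        missing_keys = sorted(set(keys[matched.isna().to_numpy()]))
        raise MissingReference(
            f"no reference Ct for (condition, timepoint, replicate) {missing_keys[:5]}"
        )
    dct = targets.assign(dct=targets["ct"].to_numpy() - matched.to_numpy())

    mean_dct = dct.groupby(["gene", "condition", "timepoint"])["dct"].mean()
    try:
        control = mean_dct.xs(control_condition, level="condition")
    except KeyError:
        raise MissingBaseline(
            f"control condition {control_condition!r} absent from Ct table"
        ) from None

    rows = []
    for (gene, cond, tp), treat_dct in mean_dct.items():
        if cond == control_condition:
            continue
        try:
            base = control.loc[(gene, tp)]
        except KeyError:
            raise MissingBaseline(
                f"no {control_condition} baseline for gene {gene!r} at {tp} h"
            ) from None
        rows.append((gene, cond, int(tp), -(treat_dct - base)))
    return pd.DataFrame(rows, columns=["gene", "condition", "timepoint", "log2fc"])


# ---------------------------------------------------------------------------
# profiles


def build_profile(
    gene: str,
    records: pd.DataFrame,
    grid: tuple[tuple[str, int], ...] = GRID,
) -> ExpressionProfile:
    """Assemble one gene's profile on the fixed grid from tidy records."""
    sub = records.loc[records["gene"] == gene]
    dup = sub.duplicated(subset=["condition", "timepoint"])
    if dup.any():
        pairs = sub.loc[dup, ["condition", "timepoint"]].to_records(index=False)
        raise AmbiguousRecord(f"gene {gene!r}: duplicate records at {list(pairs)[:3]}")
    labels = [f"{c}_{t}" for c, t in grid]
    values = pd.Series(np.nan, index=labels, dtype=float, name=gene)
    for _, row in sub.iterrows():
        label = f"{row['condition']}_{int(row['timepoint'])}"
        if label in values.index:
            values[label] = row["log2fc"]
    return ExpressionProfile(gene, values)


def build_profiles(
    records: pd.DataFrame,
    grid: tuple[tuple[str, int], ...] = GRID,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Profile matrix (genes x grid labels) from tidy log2FC records.

    Incomplete genes keep NaN cells unless ``drop_incomplete`` is set.
    """
    required = {"gene", "condition", "timepoint", "log2fc"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"records missing columns {sorted(missing)}")
    profiles = [
        build_profile(g, records, grid).values
        for g in dict.fromkeys(records["gene"])
    ]
    if not profiles:
        raise EmptyInput("no expression records")
    out = pd.DataFrame(profiles)
    out.index.name = "gene"
    if drop_incomplete:
        out = out.dropna(axis=0)
    return out


def classify_response(values: pd.Series, threshold: float = 1.0) -> pd.Series:
    """up / down / unchanged labels per grid point.

    Inclusive boundary: |log2FC| equal to the threshold counts as a
    response, so nothing silently drops at the printed cutoff.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    out = pd.Series("unchanged", index=values.index, dtype=object, name=values.name)
    out[values >= threshold] = "up"
    out[values <= -threshold] = "down"
    out[values.isna()] = "missing"
    return out


# ---------------------------------------------------------------------------
# DE table filtering


def filter_de(table: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Retain differentially expressed records with q-value strictly below
    ``q_max`` (q == q_max is excluded); fold changes pass through unmodified."""
    if "q_value" not in table.columns:
        raise InputError("DE table needs a q_value column")
    if table.empty:
        return table.copy()
    q = table["q_value"].astype(float)
    if ((q < 0) | (q > 1) | q.isna()).any():
        bad = table.index[(q < 0) | (q > 1) | q.isna()][:5].tolist()
        raise MalformedRecord(f"q_value outside [0, 1] at rows {bad}")
    return table.loc[q < q_max].copy()


# ---------------------------------------------------------------------------
# IO


def read_ct_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc


def read_log2fc_wide(path: str | Path) -> pd.DataFrame:
    """Read a wide log2FC table: gene rows, columns like ``LT_48``.

    Accepts TSV/CSV/xlsx. Column labels are normalized to the grid spelling
    (condition underscore hours).
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            table = pd.read_excel(path, index_col=0)
        else:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
            table = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except Exception as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    table.columns = [str(c).strip().replace(" ", "_") for c in table.columns]
    table.index.name = "gene"
    return table.astype(float)


def write_profiles(profiles: pd.DataFrame, path: str | Path,
                   header_note: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("# log2 fold change vs same-timepoint control\n")
        profiles.to_csv(fh, sep="\t", float_format="%.6g")
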