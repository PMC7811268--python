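"""Seeded synthetic lipidomes and expression time-courses with known truth.

The generators are statistical, not biochemical: they emulate the *shape* of
a temperature-stress glycerolipidomics + RT-qPCR study so every pipeline
stage can be exercised and its parameter recovery measured against planted
ground truth, with no external data.

Lipidome generator
------------------
Each class gets a fixed inventory of distinct ``carbons:double_bonds``
species. Baseline (control, NT) species amounts are lognormal draws around
the class abundance, tilted toward saturated species
(``exp(baseline_db_tilt * db)``); optional "major" species concentrate a
fixed fraction of a class (the handful of polyunsaturated TAGs that dominate
storage lipid, the 36:6 galactolipids). Stress conditions multiply each
class by a planted fold change and re-tilt species weights by
``exp(unsat_shift * db)`` with the class total preserved, planting a
double-bond-index increase without touching the fold change. Replicates are
the condition mean times mean-one lognormal noise of a given CV.

The default spec mirrors the study design this pipeline targets: 14 classes,
287 species, 4 replicates under LT/NT/HT, TAG folds 2.3 (LT) and 3.4 (HT)
against a baseline composition in which TAG is ~41 mol% of total
glycerolipids and PC ~64 mol% of phospholipids, and an LT unsaturation shift
calibrated to raise membrane DBI from ~2.5 to ~3.4.

Expression generator
--------------------
TF profiles are i.i.d. standard normal on the six-point
(condition, timepoint) grid. Planted target genes are
``sum(slope * TF) + N(0, noise_sd)``; decoy genes are independent standard
normal. The default panel is 17 TFs and 32 genes with 16 single-regulator
planted edges concentrated on 7 hub TFs (top hub degree 8), and noise SD
0.3287 = sqrt(1/0.95^2 - 1), i.e. a planted population correlation of 0.95
per edge.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .expression import GRID_LABELS
from .lipidome import LipidomeMatrix
from .nomenclature import CATEGORY_OF_CLASS, parse_species

__all__ = [
    "ClassSpec",
    "LipidomeSimSpec",
    "LipidomeTruth",
    "ExpressionSimSpec",
    "ExpressionTruth",
    "ExpressionSim",
    "default_lipidome_spec",
    "default_expression_spec",
    "simulate_lipidome",
    "simulate_expression",
    "write_lipidome_long",
    "write_truth",
    "read_truth",
]

_NAME_DIALECTS = ("{cls} {c}:{d}", "{cls}{c}:{d}", "{cls}({c}:{d})")


@dataclass(frozen=True)
class ClassSpec:
    """Inventory of one lipid class in the simulated panel."""

    name: str
    n_species: int
    carbon_range: tuple[int, int]      # even totals, inclusive
    max_double_bonds: int
    mean_abundance: float              # class total at control, nmol per mg DW
    major_species: tuple[tuple[int, int], ...] = ()
    major_fraction: float = 0.0        # share of class mass held by majors
    with_chains: bool = False          # emit resolved diacyl chains

    def validate(self) -> None:
        if self.name not in CATEGORY_OF_CLASS:
            raise SpecError(f"unknown class {self.name!r}")
        if self.n_species < 1:
            raise SpecError(f"{self.name}: n_species must be >= 1")
        lo, hi = self.carbon_range
        if lo % 2 or hi % 2 or lo > hi or lo < 2:
            raise SpecError(f"{self.name}: bad carbon range {self.carbon_range}")
        if self.max_double_bonds < 0:
            raise SpecError(f"{self.name}: negative max_double_bonds")
        if self.mean_abundance <= 0:
            raise SpecError(f"{self.name}: mean_abundance must be positive")
        if not 0 <= self.major_fraction < 1:
            raise SpecError(f"{self.name}: major_fraction must be in [0, 1)")
        if bool(self.major_species) != (self.major_fraction > 0):
            raise SpecError(f"{self.name}: major_species and major_fraction "
                            "must be set together")
        n_combos = ((hi - lo) // 2 + 1) * (self.max_double_bonds + 1)
        if n_combos < self.n_species:
            raise SpecError(
                f"{self.name}: only {n_combos} distinct C:D combos for "
                f"{self.n_species} species"
            )
        for c, d in self.major_species:
            if c % 2 or not lo <= c <= hi or not 0 <= d <= self.max_double_bonds:
                raise SpecError(f"{self.name}: major species {c}:{d} outside range")


@dataclass(frozen=True)
class LipidomeSimSpec:
    classes: tuple[ClassSpec, ...]
    class_fold: Mapping[str, Mapping[str, float]]   # condition -> class -> fold
    unsat_shift: Mapping[str, float]                # condition -> exp-tilt on db
    conditions: tuple[str, ...] = ("LT", "NT", "HT")
    control: str = "NT"
    n_replicates: int = 4
    cv: float = 0.10
    baseline_db_tilt: float = -0.20
    lognormal_sigma: float = 0.8       # species-to-species spread within a class
    seed: int = 0

    def validate(self) -> None:
        if not self.classes:
            raise SpecError("no classes in spec")
        for cs in self.classes:
            cs.validate()
        if self.control not in self.conditions:
            raise SpecError(f"control {self.control!r} not in conditions")
        if self.n_replicates < 1:
            raise SpecError("n_replicates must be >= 1")
        if self.cv < 0:
            raise SpecError("cv must be >= 0")
        names = {cs.name for cs in self.classes}
        for cond, folds in self.class_fold.items():
            if cond not in self.conditions:
                raise SpecError(f"fold condition {cond!r} not in conditions")
            for cls, f in folds.items():
                if cls not in names:
                    raise SpecError(f"fold for unknown class {cls!r}")
                if f <= 0:
                    raise SpecError(f"fold for {cls} must be positive, got {f}")
        for cond in self.unsat_shift:
            if cond not in self.conditions:
                raise SpecError(f"shift condition {cond!r} not in conditions")


@dataclass(frozen=True)
class LipidomeTruth:
    """Planted parameters stored alongside a generated lipidome."""

    class_fold: dict
    unsat_shift: dict
    baseline_db_tilt: float
    cv: float
    n_replicates: int
    control: str
    seed: int
    species: tuple[str, ...]           # canonical names, generation order

    kind: str = "lipidome"


def default_lipidome_spec(seed: int = 0) -> LipidomeSimSpec:
    """The default study-shaped panel: 14 classes, 287 species, 4 replicates."""
    classes = (
        ClassSpec("TAG", 90, (44, 60), 9, 12.3,
                  major_species=((52, 2), (52, 3), (52, 4),
                                 (54, 3), (54, 4), (54, 5)),
                  major_fraction=0.81),
        ClassSpec("DAG", 25, (30, 40), 6, 1.2),
        ClassSpec("MAG", 6, (14, 22), 4, 0.3),
        ClassSpec("PC", 40, (30, 40), 6, 8.7),
        ClassSpec("PI", 18, (30, 38), 6, 1.65),
        ClassSpec("PE", 30, (30, 40), 6, 1.35),
        ClassSpec("PG", 20, (30, 38), 6, 0.9),
        ClassSpec("MGDG", 12, (30, 38), 6, 1.8,
                  major_species=((36, 6),), major_fraction=0.45,
                  with_chains=True),
        ClassSpec("DGDG", 12, (30, 38), 6, 0.6,
                  major_species=((36, 6),), major_fraction=0.50,
                  with_chains=True),
        ClassSpec("PS", 10, (32, 40), 5, 0.24),
        ClassSpec("CL", 8, (60, 72), 8, 0.21),
        ClassSpec("PA", 8, (30, 38), 5, 0.24),
        ClassSpec("LPE", 4, (14, 20), 3, 0.21),
        ClassSpec("DGTS", 4, (38, 44), 5, 0.3),
    )
    class_fold = {
        "LT": {"TAG": 2.3, "DAG": 1.1, "MAG": 1.0, "PC": 0.65, "PI": 0.7,
               "PE": 0.65, "PG": 1.1, "MGDG": 0.65, "DGDG": 0.8, "PS": 1.4,
               "CL": 0.9, "PA": 1.0, "LPE": 0.9, "DGTS": 1.5},
        "HT": {"TAG": 3.4, "DAG": 1.1, "MAG": 1.0, "PC": 0.65, "PI": 0.7,
               "PE": 0.65, "PG": 0.7, "MGDG": 0.75, "DGDG": 0.85, "PS": 1.3,
               "CL": 0.8, "PA": 1.8, "LPE": 0.9, "DGTS": 1.4},
    }
    unsat_shift = {"LT": 0.25, "HT": 0.03}
    return LipidomeSimSpec(classes=classes, class_fold=class_fold,
                           unsat_shift=unsat_shift, seed=seed)


def _format_name(rng: np.random.Generator, cls: str, c: int, d: int,
                 chains: tuple[tuple[int, int], ...] | None) -> str:
    tpl = _NAME_DIALECTS[rng.integers(len(_NAME_DIALECTS))]
    name = tpl.format(cls=cls, c=c, d=d)
    if chains:
        name += "(" + "/".join(f"{cc}:{dd}" for cc, dd in chains) + ")"
    return name


def _split_chains(rng: np.random.Generator, c: int, d: int
                  ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Split a diacyl total into two plausible chains summing exactly."""
    if (c, d) == (36, 6):
        return ((18, 3), (18, 3))
    lo = max(14, c - 22)
    hi = min(22, c - 14)
    choices = [x for x in range(lo, hi + 1, 2)]
    c1 = int(rng.choice(choices))
    c2 = c - c1
    d1 = int(rng.integers(0, d + 1))
    d1 = min(d1, c1 - 1)
    d2 = d - d1
    if d2 >= c2:  # push overflow back onto the first chain
        d1, d2 = d - (c2 - 1), c2 - 1
    return ((c1, d1), (c2, d2))


def simulate_lipidome(spec: LipidomeSimSpec
                      ) -> tuple[LipidomeMatrix, LipidomeTruth]:
    """Generate a lipidome matrix plus its planted truth, reproducibly."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    names: list[str] = []
    raw_rows: list[dict] = []
    for cs in spec.classes:
        lo, hi = cs.carbon_range
        combos = [(c, d) for c in range(lo, hi + 1, 2)
                  for d in range(cs.max_double_bonds + 1)]
        majors = list(cs.major_species)
        minors = [cd for cd in combos if cd not in majors]
        n_minor = cs.n_species - len(majors)
        idx = rng.choice(len(minors), size=n_minor, replace=False)
        chosen = majors + [minors[i] for i in sorted(idx)]

        weights = rng.lognormal(mean=0.0, sigma=spec.lognormal_sigma,
                                size=len(chosen))
        dbs = np.array([d for _, d in chosen], dtype=float)
        weights = weights * np.exp(spec.baseline_db_tilt * dbs)
        if majors:
            wm = weights[: len(majors)]
            wr = weights[len(majors):]
            weights = np.concatenate([
                wm / wm.sum() * cs.major_fraction,
                wr / wr.sum() * (1.0 - cs.major_fraction),
            ])
        else:
            weights = weights / weights.sum()
        base_amounts = weights * cs.mean_abundance

        for (c, d), amount in zip(chosen, base_amounts):
            chains = _split_chains(rng, c, d) if cs.with_chains else None
            raw = _format_name(rng, cs.name, c, d, chains)
            raw_rows.append({
                "class": cs.name, "carbons": c, "db": d,
                "raw_name": raw, "baseline": amount,
            })
            names.append(raw)

    table = pd.DataFrame(raw_rows)
    cond_means = {}
    for cond in spec.conditions:
        tilt = spec.unsat_shift.get(cond, 0.0) if cond != spec.control else 0.0
        folds = spec.class_fold.get(cond, {}) if cond != spec.control else {}
        means = np.empty(len(table))
        for cls, sub in table.groupby("class", sort=False):
            w = sub["baseline"].to_numpy() * np.exp(tilt * sub["db"].to_numpy())
            w = w / w.sum() * sub["baseline"].sum()  # class total preserved
            means[sub.index] = w * folds.get(cls, 1.0)
        cond_means[cond] = means

    sigma = float(np.sqrt(np.log1p(spec.cv**2)))
    columns = []
    data = []
    for cond in spec.conditions:
        noise = rng.normal(0.0, 1.0, size=(len(table), spec.n_replicates))
        factors = np.exp(sigma * noise - 0.5 * sigma**2) if sigma > 0 else \
            np.ones_like(noise)
        for rep in range(1, spec.n_replicates + 1):
            columns.append((cond, rep))
            data.append(cond_means[cond] * factors[:, rep - 1])

    species = [parse_species(n) for n in names]
    amounts = pd.DataFrame(
        np.column_stack(data),
        index=[sp.canonical() for sp in species],
        columns=pd.MultiIndex.from_tuples(columns,
                                          names=["condition", "replicate"]),
    )
    matrix = LipidomeMatrix(species, amounts)
    truth = LipidomeTruth(
        class_fold={c: dict(f) for c, f in spec.class_fold.items()},
        unsat_shift=dict(spec.unsat_shift),
        baseline_db_tilt=spec.baseline_db_tilt,
        cv=spec.cv,
        n_replicates=spec.n_replicates,
        control=spec.control,
        seed=spec.seed,
        species=tuple(sp.canonical() for sp in species),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionSimSpec:
    n_tfs: int = 17
    n_genes: int = 32
    planted_edges: tuple[tuple[str, str, float], ...] = ()
    #: per-point Gaussian noise on planted targets; the default plants a
    #: population correlation of 0.95 per edge (sd = sqrt(1/0.95^2 - 1)).
    noise_sd: float = 0.3287
    grid: tuple[str, ...] = GRID_LABELS
    seed: int = 0

    def tf_ids(self) -> tuple[str, ...]:
        return tuple(f"TF{i:02d}" for i in range(1, self.n_tfs + 1))

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i:02d}" for i in range(1, self.n_genes + 1))

    def validate(self) -> None:
        if self.n_tfs < 1 or self.n_genes < 1:
            raise SpecError("need at least one TF and one gene")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if len(self.grid) < 3:
            raise SpecError("grid needs at least 3 points")
        tfs, genes = set(self.tf_ids()), set(self.gene_ids())
        for tf, gene, slope in self.planted_edges:
            if tf not in tfs:
                raise SpecError(f"planted edge references unknown TF {tf!r}")
            if gene not in genes:
                raise SpecError(f"planted edge references unknown gene {gene!r}")
            if slope == 0:
                raise SpecError(f"planted edge ({tf}, {gene}) has zero slope")


@dataclass(frozen=True)
class ExpressionTruth:
    planted_edges: tuple[tuple[str, str, float], ...]
    noise_sd: float
    seed: int
    kind: str = "expression"


@dataclass(frozen=True)
class ExpressionSim:
    tf_profiles: pd.DataFrame
    gene_profiles: pd.DataFrame
    truth: ExpressionTruth


#: Hub out-degrees of the default planted network (7 hubs, 16 targets).
_DEFAULT_HUB_DEGREES = (8, 2, 2, 1, 1, 1, 1)


def default_expression_spec(seed: int = 0, noise_sd: float = 0.3287
                            ) -> ExpressionSimSpec:
    """17 TFs x 32 genes; 16 single-regulator edges on 7 hub TFs (top hub
    regulates 8 genes); remaining genes and TFs are independent decoys."""
    edges = []
    gene_no = 1
    for hub_idx, degree in enumerate(_DEFAULT_HUB_DEGREES, start=1):
        for _ in range(degree):
            edges.append((f"TF{hub_idx:02d}", f"G{gene_no:02d}", 1.0))
            gene_no += 1
    return ExpressionSimSpec(planted_edges=tuple(edges), noise_sd=noise_sd,
                             seed=seed)


def simulate_expression(spec: ExpressionSimSpec) -> ExpressionSim:
    """Generate TF and gene log2FC profile matrices plus planted truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.grid)
    n = len(labels)

    tf_ids = spec.tf_ids()
    tf_matrix = rng.standard_normal((len(tf_ids), n))
    tf_profiles = pd.DataFrame(tf_matrix, index=list(tf_ids), columns=labels)
    tf_profiles.index.name = "gene"

    regulators: dict[str, list[tuple[str, float]]] = {}
    for tf, gene, slope in spec.planted_edges:
        regulators.setdefault(gene, []).append((tf, slope))

    rows = []
    for gene in spec.gene_ids():
        if gene in regulators:
            profile = np.zeros(n)
            for tf, slope in regulators[gene]:
                profile = profile + slope * tf_profiles.loc[tf].to_numpy()
            profile = profile + rng.normal(0.0, spec.noise_sd, size=n)
        else:
            profile = rng.standard_normal(n)
        rows.append(profile)
    gene_profiles = pd.DataFrame(rows, index=list(spec.gene_ids()),
                                 columns=labels)
    gene_profiles.index.name = "gene"

    truth = ExpressionTruth(planted_edges=spec.planted_edges,
                            noise_sd=spec.noise_sd, seed=spec.seed)
    return ExpressionSim(tf_profiles, gene_profiles, truth)


# ---------------------------------------------------------------------------
# serialization


def write_lipidome_long(matrix: LipidomeMatrix, path: str | Path) -> None:
    """Long-format TSV (species, condition, replicate, amount), the same
    layout the pipeline consumes. Amounts in nmol per mg dry weight."""
    long = matrix.to_long()
    with open(path, "w") as fh:
        fh.write("# amount units: nmol per mg dry weight\n")
        long.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_truth(truth: LipidomeTruth | ExpressionTruth, path: str | Path) -> None:
    payload = asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> LipidomeTruth | ExpressionTruth:
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.pop("kind", None)
    if kind == "lipidome":
        payload["species"] = tuple(payload["species"])
        return LipidomeTruth(**payload)
    if kind == "expression":
        payload["planted_edges"] = tuple(
            (tf, gene, float(slope)) for tf, gene, slope in payload["planted_edges"]
        )
        return ExpressionTruth(**payload)
    raise ValueError(f"unknown truth kind {kind!r} in {path}")
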