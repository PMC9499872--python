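"""Core data containers: twin cohorts, orientations and discordance matrices.

A :class:`TwinCohort` bundles per-individual phenotypes (one row per
individual, with pair membership and zygosity), an optional log2-normalized
expression matrix (genes x individuals) and optional ground-truth labels
from the synthetic generator.  A :class:`DiscordanceMatrix` holds per-pair
log-scale heavy-minus-light differences together with the orientation that
produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Columns of the phenotype table that are metadata, not traits.
META_COLUMNS = ("pair", "zygosity", "sex", "age")


@dataclass
class TwinCohort:
    """A twin cohort: phenotypes, optional expression, optional truth labels.

    Parameters
    ----------
    phenotypes
        DataFrame indexed by individual ID with columns ``pair``,
        ``zygosity`` (``MZ``/``DZ``), ``sex``, ``age`` and one column per
        trait (positive reals; mass in kg, height in m, BMI in kg/m^2).
    expression
        Optional genes x individuals DataFrame of log2-normalized values.
        Columns must be a subset of the phenotype individuals.
    trait_names
        Trait columns, in panel order.
    truth
        Optional ground truth from the simulator: ``pair_group`` maps pair
        -> planted group, ``gene_role`` maps gene -> planted role,
        ``nnat_like_gene`` names the designated down-regulated gene,
        ``morph`` maps individual -> planted heavy/light state.
    """

    phenotypes: pd.DataFrame
    expression: pd.DataFrame | None = None
    trait_names: list[str] = field(default_factory=list)
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.trait_names:
            self.trait_names = [
                c for c in self.phenotypes.columns if c not in META_COLUMNS
            ]

    # -- accessors ---------------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.phenotypes.index)

    @property
    def pairs(self) -> list[str]:
        return list(pd.unique(self.phenotypes["pair"]))

    def members(self, pair: str) -> list[str]:
        """The two individual IDs of a pair, in index order."""
        return list(self.phenotypes.index[self.phenotypes["pair"] == pair])

    def traits(self) -> pd.DataFrame:
        """Individual x trait matrix."""
        return self.phenotypes[self.trait_names]

    def zygosity_of(self, pair: str) -> str:
        return str(self.phenotypes.loc[self.members(pair)[0], "zygosity"])

    def subset_pairs(self, pairs) -> "TwinCohort":
        keep = self.phenotypes["pair"].isin(list(pairs))
        pheno = self.phenotypes.loc[keep]
        expr = None
        if self.expression is not None:
            cols = [c for c in self.expression.columns if c in set(pheno.index)]
            expr = self.expression[cols]
        return TwinCohort(pheno, expr, list(self.trait_names), self.truth)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` on any invariant violation."""
        counts = self.phenotypes["pair"].value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise ConfigurationError(
                f"pairs without exactly 2 members: {sorted(bad.index.tolist())}"
            )
        for col in ("pair", "zygosity", "sex", "age"):
            if col not in self.phenotypes.columns:
                raise ConfigurationError(f"phenotypes missing column {col!r}")
        for pair in self.pairs:
            a, b = self.members(pair)
            pheno = self.phenotypes
            if pheno.loc[a, "age"] != pheno.loc[b, "age"]:
                raise ConfigurationError(f"co-twins of pair {pair!r} differ in age")
            if pheno.loc[a, "sex"] != pheno.loc[b, "sex"]:
                raise ConfigurationError(f"co-twins of pair {pair!r} differ in sex")
        mass_like = [
            t
            for t in self.trait_names
            if t == "bmi" or t == "height" or t == "weight" or "mass" in t
        ]
        vals = self.phenotypes[mass_like].to_numpy(dtype=float)
        if np.any(~np.isnan(vals) & (vals <= 0)):
            raise ConfigurationError("mass/height/BMI values must be > 0")
        if self.expression is not None:
            extra = set(self.expression.columns) - set(self.phenotypes.index)
            if extra:
                raise ConfigurationError(
                    f"expression columns not in cohort: {sorted(extra)}"
                )


@dataclass
class Orientation:
    """BMI-ordered heavy/light orientation of co-twin pairs.

    ``table`` is indexed by pair with columns ``light``, ``heavy`` and
    ``tie`` (True where the reference trait tied and the lexicographic rule
    was applied).  ``rejects`` lists (pair, reason) for dropped pairs.
    """

    table: pd.DataFrame
    reference_trait: str = "bmi"
    rejects: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pairs(self) -> list[str]:
        return list(self.table.index)

    def light(self, pair: str) -> str:
        return str(self.table.loc[pair, "light"])

    def heavy(self, pair: str) -> str:
        return str(self.table.loc[pair, "heavy"])

    def flipped(self) -> "Orientation":
        """Orientation with light/heavy swapped for every pair (for tests)."""
        tab = self.table.copy()
        tab[["light", "heavy"]] = tab[["heavy", "light"]].to_numpy()
        return Orientation(tab, self.reference_trait, list(self.rejects))


@dataclass
class DiscordanceMatrix:
    """Pair x trait (or gene) log-scale discordance matrix.

    ``values`` rows are pairs, columns traits/genes; entry = log(heavy) -
    log(light) in base ``log_base`` ("e" or "2").
    """

    values: pd.DataFrame
    orientation: Orientation
    log_base: str = "e"

    def __post_init__(self) -> None:
        if self.log_base not in ("e", "2"):
            raise ConfigurationError(f"log_base must be 'e' or '2', got {self.log_base!r}")

    @property
    def pairs(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def dropna_pairs(self) -> "DiscordanceMatrix":
        vals = self.values.dropna(axis=0)
        ori = Orientation(
            self.orientation.table.loc[vals.index],
            self.orientation.reference_trait,
            list(self.orientation.rejects),
        )
        return DiscordanceMatrix(vals, ori, self.log_base)
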