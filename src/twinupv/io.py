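"""File readers and writers (TSV, GMT, JSON sidecars).

All tabular files are tab-delimited UTF-8 with a header row and "."
decimal separator.  A cohort round-trips as three files: phenotypes.tsv
(one row per individual), expression.tsv (genes x individuals) and
truth.json (optional ground-truth labels).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DiscordanceMatrix, Orientation, TwinCohort
from .enrichment import GeneSet
from .errors import ConfigurationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: per line, name TAB description TAB members...

    Duplicate members within a set are de-duplicated with a warning; a
    line with fewer than three fields is a parse error naming the line.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                log.warning("%s line %d: duplicate members in set %s", path, lineno, name)
            sets.append(GeneSet(name, desc, tuple(uniq)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: TwinCohort, outdir) -> dict[str, Path]:
    """Write phenotypes.tsv, expression.tsv and truth.json; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pheno_path = outdir / "phenotypes.tsv"
    cohort.phenotypes.to_csv(pheno_path, sep="\t", index_label="individual")
    paths["phenotypes"] = pheno_path
    if cohort.expression is not None:
        expr_path = outdir / "expression.tsv"
        cohort.expression.to_csv(expr_path, sep="\t", index_label="gene")
        paths["expression"] = expr_path
    if cohort.truth is not None:
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(cohort.truth, indent=1), encoding="utf-8")
        paths["truth"] = truth_path
    return paths


def read_cohort(phenotypes_path, expression_path=None, truth_path=None) -> TwinCohort:
    """Read and validate a cohort from its TSV/JSON files.

    Individuals missing from the expression matrix are retained (their
    expression is simply absent).  Pairs without exactly two members and
    non-numeric trait cells are errors naming the offenders.
    """
    pheno = pd.read_csv(phenotypes_path, sep="\t", index_col="individual")
    required = ["pair", "zygosity", "sex", "age", "bmi"]
    missing = [c for c in required if c not in pheno.columns]
    if missing:
        raise ConfigurationError(f"{phenotypes_path}: missing columns {missing}")
    trait_cols = [c for c in pheno.columns if c not in ("pair", "zygosity", "sex", "age")]
    for col in trait_cols:
        coerced = pd.to_numeric(pheno[col], errors="coerce")
        bad = pheno.index[coerced.isna() & pheno[col].notna()]
        if len(bad):
            raise ConfigurationError(
                f"{phenotypes_path}: non-numeric value in column {col!r}, row {bad[0]!r}"
            )
        pheno[col] = coerced
    counts = pheno["pair"].value_counts()
    bad_pairs = sorted(counts.index[counts != 2].tolist())
    if bad_pairs:
        raise ConfigurationError(f"pairs without exactly 2 members: {bad_pairs}")
    expr = None
    if expression_path is not None:
        expr = pd.read_csv(expression_path, sep="\t", index_col="gene")
        extra = set(expr.columns) - set(pheno.index)
        if extra:
            raise ConfigurationError(
                f"{expression_path}: columns not in cohort: {sorted(extra)[:5]}"
            )
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = json.loads(Path(truth_path).read_text(encoding="utf-8"))
    cohort = TwinCohort(pheno, expr, trait_cols, truth)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# discordance matrices
# ---------------------------------------------------------------------------

def write_discordance(D: DiscordanceMatrix, values_path, orientation_path) -> None:
    D.values.to_csv(values_path, sep="\t", index_label="pair")
    tab = D.orientation.table.copy()
    tab["log_base"] = D.log_base
    tab.to_csv(orientation_path, sep="\t", index_label="pair")


def read_discordance(values_path, orientation_path) -> DiscordanceMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="pair")
    tab = pd.read_csv(orientation_path, sep="\t", index_col="pair")
    log_base = str(tab["log_base"].iloc[0]) if "log_base" in tab.columns else "e"
    tab = tab[[c for c in ("light", "heavy", "tie") if c in tab.columns]]
    return DiscordanceMatrix(values, Orientation(tab), log_base)


def write_mouse_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mouse_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("fat_mass", "lean_mass"):
        if col not in table.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
        if (table[col] <= 0).any():
            raise ConfigurationError(f"{path}: nonpositive {col}")
    return table
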