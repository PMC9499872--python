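"""Pipeline orchestration: discordance -> typing -> signature -> strata ->
enrichment -> association, with a hashed manifest for partial reruns.

Each stage writes its outputs under the configured output directory and
records them (with content hashes and the parameter/input hash that
produced them) in ``manifest.json``.  A rerun skips stages whose key and
outputs are unchanged and recomputes from the first invalidated stage
onward.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import discordance as disc
from . import enrichment as enr
from . import io as tio
from . import pair_typing as typing_
from . import signature as sig
from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, trait tags and per-stage parameters of the full pipeline."""

    phenotypes: str = ""
    expression: str | None = None
    gene_sets: str | None = None
    outdir: str = "twinupv_out"
    fat_traits: list[str] = field(default_factory=list)
    lean_traits: list[str] = field(default_factory=list)
    reference_trait: str = "bmi"
    k_neighbors: int = 20
    resolution: float = 0.8
    n_null: int = 10
    umap_neighbors: int = 15
    min_dist: float = 0.1
    alpha: float = 0.001
    gene_kmeans_k: int = 2
    k_max: int = 10
    n_boot: int = 50
    n_perm: int = 4000
    padj_cutoff: float = 0.01
    nnat_gene: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.phenotypes or not Path(self.phenotypes).exists():
            raise ConfigurationError(f"phenotypes path does not exist: {self.phenotypes!r}")
        for name in ("expression", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(params: dict, inputs: list[Path]) -> str:
    payload = {"params": params, "inputs": {str(p): _sha256(p) for p in inputs if p and Path(p).exists()}}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text(encoding="utf-8"))

    def fresh(self, stage: str, key: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry or entry.get("key") != key:
            return False
        for rel, digest in entry.get("outputs", {}).items():
            p = self.path.parent / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, key: str, outputs: list[Path], params: dict) -> None:
        self.data["stages"][stage] = {
            "key": key,
            "params": {k: str(v) for k, v in params.items()},
            "outputs": {
                str(p.relative_to(self.path.parent)): _sha256(p) for p in outputs
            },
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True), encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict.

    Stage errors abort with the stage name; outputs of earlier stages are
    preserved.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    cohort = tio.read_cohort(
        config.phenotypes,
        config.expression,
        Path(config.phenotypes).parent / "truth.json",
    )
    fat = config.fat_traits or [t for t in cohort.trait_names if t.startswith("fat_")]
    lean = config.lean_traits or [t for t in cohort.trait_names if t.startswith("lean_")]

    state: dict = {"cohort": cohort, "fat": fat, "lean": lean}
    stages = [
        ("discordance", _stage_discordance),
        ("typing", _stage_typing),
        ("signature", _stage_signature),
        ("stratify", _stage_stratify),
        ("enrichment", _stage_enrichment),
        ("association", _stage_association),
    ]
    upstream_ran = False
    for name, fn in stages:
        params = {
            k: getattr(config, k)
            for k in config.__dataclass_fields__
            if k not in ("outdir", "log_level")
        }
        params["stage"] = name
        inputs = [Path(config.phenotypes)]
        if config.expression:
            inputs.append(Path(config.expression))
        if config.gene_sets:
            inputs.append(Path(config.gene_sets))
        key = _stage_key(params, inputs)
        # a stage that re-ran invalidates everything downstream (in-memory
        # state may have changed even if inputs did not)
        if not upstream_ran and manifest.fresh(name, key):
            log.info("stage %s: up to date, skipped", name)
            _reload_stage(name, out, state, config)
            continue
        log.info("stage %s: running", name)
        try:
            outputs = fn(config, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, key, outputs, {"stage": name})
        upstream_ran = True
    return manifest.data


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_discordance(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = state["cohort"]
    orientation = disc.assign_reference(cohort, cfg.reference_trait)
    # insulin is analyzed separately (association stage), not clustered on
    traits = [t for t in cohort.trait_names if t != "insulin"]
    D = disc.trait_discordance(cohort, orientation, traits).dropna_pairs()
    mz_pairs = [p for p in D.pairs if cohort.zygosity_of(p) == "MZ"]
    dz_pairs = [p for p in D.pairs if cohort.zygosity_of(p) == "DZ"]
    Dmz = typing_.DiscordanceMatrix(
        D.values.loc[mz_pairs],
        disc.Orientation(orientation.table.loc[mz_pairs], cfg.reference_trait),
        D.log_base,
    )
    state["orientation"] = orientation
    state["D_mz"] = Dmz
    outputs = []
    p1, p2 = out / "trait_discordance.tsv", out / "orientation.tsv"
    tio.write_discordance(Dmz, p1, p2)
    outputs += [p1, p2]
    if dz_pairs:
        Ddz = typing_.DiscordanceMatrix(
            D.values.loc[dz_pairs],
            disc.Orientation(orientation.table.loc[dz_pairs], cfg.reference_trait),
            D.log_base,
        )
        tab = disc.zygosity_discordance_test(Dmz, Ddz)
        p3 = out / "mz_dz_test.tsv"
        tab.to_csv(p3, sep="\t", index=False)
        outputs.append(p3)
    return outputs


def _stage_typing(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    D = state["D_mz"]
    null = typing_.cluster_stability_null(
        D, cfg.k_neighbors, cfg.resolution, cfg.seed, n_null=cfg.n_null
    )
    if null["stable"]:
        labels = null["labels"]
    else:
        log.warning("no stable cluster structure; all pairs assigned one cluster")
        labels = pd.Series(0, index=D.values.index, name="cluster")
    clustering = typing_.assign_cluster_types(labels, D, state["fat"], state["lean"])
    embedding = typing_.embed_pairs(
        D, min(cfg.umap_neighbors, len(D.pairs) - 1), cfg.min_dist, cfg.seed
    )
    clustering.embedding = embedding
    order = typing_.heatmap_order(D)
    state["clustering"] = clustering
    p1 = out / "clusters.tsv"
    pd.DataFrame({"cluster": clustering.labels, "type": clustering.pair_types}).to_csv(
        p1, sep="\t", index_label="pair"
    )
    p2 = out / "embedding.tsv"
    embedding.to_csv(p2, sep="\t", index_label="pair")
    p3 = out / "heatmap_order.json"
    p3.write_text(
        json.dumps(
            {
                "row_order": [str(r) for r in order.row_order],
                "col_order": [str(c) for c in order.col_order],
                "stable": null["stable"],
                "observed_modularity": null["observed_modularity"],
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    return [p1, p2, p3]


def _stage_signature(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = state["cohort"]
    if cohort.expression is None:
        log.warning("no expression matrix; signature stage writes empty outputs")
        p = out / "signature.tsv"
        pd.DataFrame(columns=["direction"]).to_csv(p, sep="\t", index_label="gene")
        state["signature"] = None
        return [p]
    clustering = state["clustering"]
    ages = pd.DataFrame(
        {
            "age": [
                float(cohort.phenotypes.loc[state["orientation"].heavy(p), "age"])
                for p in clustering.labels.index
            ]
        },
        index=clustering.labels.index,
    )
    de = sig.paired_moderated_de(
        cohort.expression, state["orientation"], clustering.labels, covariates=ages
    )
    outputs = []
    for cluster, table in de.items():
        p = out / f"de_cluster{cluster}.tsv"
        table.to_csv(p, sep="\t")
        outputs.append(p)
    typeb = [c for c, t in clustering.cluster_types.items() if t == "TypeB"]
    if typeb and typeb[0] in de:
        signature = sig.derive_typeB_signature(
            de, typeb[0], alpha=cfg.alpha, gene_kmeans_k=cfg.gene_kmeans_k, seed=cfg.seed
        )
    else:
        log.warning("no TypeB cluster; empty signature")
        empty = pd.DataFrame(columns=["direction"])
        empty.index.name = "gene"
        signature = sig.Signature(empty, cfg.alpha, None)
    state["de"] = de
    state["signature"] = signature
    p = out / "signature.tsv"
    signature.genes.to_csv(p, sep="\t", index_label="gene")
    outputs.append(p)
    return outputs


def _stage_stratify(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = state["cohort"]
    signature = state.get("signature")
    p1 = out / "strata.tsv"
    if signature is None or len(signature) == 0 or cohort.expression is None:
        log.warning("empty signature; stratification skipped")
        pd.DataFrame(columns=["cluster", "upvb_rank"]).to_csv(
            p1, sep="\t", index_label="individual"
        )
        state["strata"] = None
        return [p1]
    strat = sig.stratify_individuals(
        cohort.expression,
        signature,
        k_max=cfg.k_max,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        phenotypes=cohort.phenotypes,
    )
    ranks = sig.upvb_rank(cohort.expression, signature)
    state["strata"] = strat
    state["upvb_rank"] = ranks
    pd.DataFrame({"cluster": strat.clusters, "upvb_rank": ranks}).loc[strat.order].to_csv(
        p1, sep="\t", index_label="individual"
    )
    p2 = out / "dispersion.tsv"
    strat.dispersion.to_csv(p2, sep="\t", index_label="k", header=["wss"])
    pc = sig.pc_signature_contribution(cohort.expression, signature.gene_names)
    p3 = out / "pc_contribution.json"
    p3.write_text(
        json.dumps(
            {
                "chosen_k": strat.chosen_k,
                "stability": (
                    {str(k): v for k, v in strat.stability.items()}
                    if strat.stability is not None
                    else None
                ),
                "selected_pcs": pc.selected_pcs,
                "cumulative_variance_fraction": pc.cumulative_variance_fraction,
                "uninformative": pc.uninformative,
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    return [p1, p2, p3]


def _stage_enrichment(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    p1 = out / "enrichment.tsv"
    if not cfg.gene_sets or "de" not in state:
        log.warning("no gene sets or DE tables; enrichment skipped")
        pd.DataFrame(columns=["name", "es", "nes", "p", "padj", "size"]).to_csv(
            p1, sep="\t", index=False
        )
        return [p1]
    clustering = state["clustering"]
    typeb = [c for c, t in clustering.cluster_types.items() if t == "TypeB"]
    de = state["de"]
    cluster = typeb[0] if typeb and typeb[0] in de else None
    if cluster is None:
        log.warning("no TypeB DE table; enrichment skipped")
        pd.DataFrame(columns=["name", "es", "nes", "p", "padj", "size"]).to_csv(
            p1, sep="\t", index=False
        )
        return [p1]
    sets = tio.read_gmt(cfg.gene_sets)
    ranked = de[cluster]["t"]
    results = enr.preranked_enrichment(
        ranked, sets, n_perm=cfg.n_perm, seed=cfg.seed
    )
    pd.DataFrame(
        [
            {
                "name": r.name,
                "es": r.es,
                "nes": r.nes,
                "p": r.p,
                "padj": r.padj,
                "size": r.size,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ]
    ).to_csv(p1, sep="\t", index=False)
    hdac = enr.derive_hdac_signature(results, padj_cutoff=cfg.padj_cutoff)
    state["hdac_signature"] = hdac
    outputs = [p1]
    p2 = out / "hdac_signature.gmt"
    if len(hdac):
        tio.write_gmt([hdac], p2)
        outputs.append(p2)
        cohort = state["cohort"]
        if cohort.expression is not None:
            scores = enr.signature_score(cohort.expression, hdac)
            p3 = out / "hdac_scores.tsv"
            scores.to_csv(p3, sep="\t", index_label="individual")
            state["hdac_scores"] = scores
            outputs.append(p3)
    return outputs


def _stage_association(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = state["cohort"]
    clustering = state["clustering"]
    pheno = cohort.phenotypes
    outputs = []
    # insulin ~ BMI per UPV type
    if "insulin" in pheno.columns:
        ind_type = pheno["pair"].map(
            clustering.pair_types.reindex(clustering.labels.index)
        )
        fits = assoc.group_linear_fit(pheno["insulin"], pheno["bmi"], ind_type)
        p1 = out / "group_fits.tsv"
        fits.to_csv(p1, sep="\t", index=False)
        outputs.append(p1)
        state["group_fits"] = fits
    signature = state.get("signature")
    if cohort.expression is not None and signature is not None and len(signature):
        orientation = state["orientation"]
        Dg = disc.expression_discordance(cohort, orientation)
        pairs = clustering.labels.index
        keep = [g for g in signature.gene_names]
        Dg_sub = typing_.DiscordanceMatrix(
            Dg.values.loc[[p for p in pairs if p in set(Dg.pairs)], keep],
            Dg.orientation,
            "2",
        )
        cmap = assoc.discordance_spearman(Dg_sub, state["D_mz"], clustering.labels)
        p2 = out / "correlation_map.tsv"
        cmap.neglog10p.to_csv(p2, sep="\t", index_label="gene")
        outputs.append(p2)
        # variance tests and quantile split on the designated buffer gene
        gene = cfg.nnat_gene
        if gene is None:
            downs = signature.genes.index[signature.genes["direction"] == "down_in_heavy"]
            gene = downs[0] if len(downs) else None
        if gene is not None and gene in cohort.expression.index:
            level = pd.Series(
                {
                    p: float(
                        cohort.expression.loc[
                            gene, [orientation.light(p), orientation.heavy(p)]
                        ].mean()
                    )
                    for p in pairs
                    if p in set(Dg.pairs)
                }
            )
            if "insulin" in pheno.columns:
                ins_d = pd.Series(
                    {
                        p: float(
                            np.log2(pheno.loc[orientation.heavy(p), "insulin"])
                            - np.log2(pheno.loc[orientation.light(p), "insulin"])
                        )
                        for p in level.index
                    }
                )
                qs = assoc.quantile_split_mixture(level, ins_d, seed=cfg.seed)
                p3 = out / "quantile_split.tsv"
                pd.DataFrame({"half": qs.half, "assignment": qs.assignment}).to_csv(
                    p3, sep="\t", index_label="pair"
                )
                outputs.append(p3)
                bmi_d = state["D_mz"].values["bmi"] if "bmi" in state["D_mz"].columns else None
                if bmi_d is not None:
                    common = [p for p in qs.half.index if p in bmi_d.index]
                    stat, pv = assoc.variance_homogeneity(
                        bmi_d.loc[common].abs(), qs.half.loc[common], method="bartlett"
                    )
                    p4 = out / "variance_tests.tsv"
                    pd.DataFrame(
                        [{"test": "bartlett_bmi_discordance_by_half", "statistic": stat, "p": pv}]
                    ).to_csv(p4, sep="\t", index=False)
                    outputs.append(p4)
    return outputs


def _reload_stage(name: str, out: Path, state: dict, cfg: PipelineConfig) -> None:
    """Repopulate in-memory state from a skipped (cached) stage's outputs."""
    if name == "discordance":
        D = tio.read_discordance(out / "trait_discordance.tsv", out / "orientation.tsv")
        state["D_mz"] = D
        state["orientation"] = disc.assign_reference(state["cohort"], cfg.reference_trait)
    elif name == "typing":
        tab = pd.read_csv(out / "clusters.tsv", sep="\t", index_col="pair")
        labels = tab["cluster"]
        clustering = typing_.assign_cluster_types(
            labels, state["D_mz"], state["fat"], state["lean"]
        )
        state["clustering"] = clustering
    elif name == "signature":
        genes = pd.read_csv(out / "signature.tsv", sep="\t", index_col="gene")
        state["signature"] = sig.Signature(genes, cfg.alpha, None) if len(genes) else None
        de = {}
        for p in out.glob("de_cluster*.tsv"):
            cluster = int(p.stem.replace("de_cluster", ""))
            de[cluster] = pd.read_csv(p, sep="\t", index_col="gene")
        if de:
            state["de"] = de
    elif name == "stratify" and (out / "strata.tsv").exists():
        state["strata_table"] = pd.read_csv(out / "strata.tsv", sep="\t", index_col="individual")
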