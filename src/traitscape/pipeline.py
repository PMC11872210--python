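"""End-to-end pipeline driver: synthesize (or load) inputs, run the SSR
and trait analyses, and write every intermediate table plus a
machine-readable run manifest.

Re-running with an identical config and seed is byte-identical on all
CSV outputs; the manifest records the config hash, seed, library
versions, per-stage record counts and every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import fit_leaf_area, reference_model
from .inference import factorial_anova, one_way_anova
from .plasticity import (ambient_scores_by_individual, plasticity_by_contrast,
                         trait_variation_index)
from .scape import IterativePCAImputer, TraitScapePCA
from .ssr import (call_multilocus_genotypes, dissimilarity_matrix,
                  frequency_table, locus_columns, minimum_spanning_network)
from .synth import (ALL_TRAITS, FUNCTIONAL_TRAITS, DesignSpec, TraitModel,
                    default_trait_model, generate_greenhouse, generate_leaves,
                    generate_ssr)

log = logging.getLogger("traitscape")

STAGES = ("synth", "ssr", "impute", "scape", "plasticity", "anova", "allometry")


@dataclass
class PipelineConfig:
    """Run configuration; mirrors the YAML/JSON config file."""

    seed: int = 0
    outdir: str = "runs/latest"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    figures: bool = False
    design: dict[str, Any] = field(default_factory=dict)
    ssr_synth: dict[str, Any] = field(default_factory=dict)
    impute_params: dict[str, Any] = field(
        default_factory=lambda: {"n_components": 2, "max_iter": 1000, "tol": 1e-8})
    pca: dict[str, Any] = field(default_factory=lambda: {"scale": True})
    anova: dict[str, Any] = field(
        default_factory=lambda: {"responses": list(ALL_TRAITS), "boxcox": True})
    inputs: dict[str, str | None] = field(
        default_factory=lambda: {"traits": None, "ssr": None, "leaves": None})

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, Mapping):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        unknown = set(cfg.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if any(cfg.stages.values()) and cfg.seed is None:
            raise ValueError("seed is mandatory when any stage is enabled")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed, "outdir": str(self.outdir), "stages": self.stages,
            "figures": self.figures, "design": self.design,
            "ssr_synth": self.ssr_synth, "impute_params": self.impute_params,
            "pca": self.pca, "anova": self.anova, "inputs": self.inputs,
        }


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict, index=False) -> None:
    df.to_csv(path, index=index)
    manifest["outputs"].append(path.name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the manifest (also written
    to ``<outdir>/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "traitscape",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {s: bool(config.stages.get(s, False)) for s in STAGES},
        "counts": {},
        "outputs": [],
    }
    enabled = manifest["stages"]
    t0 = time.time()

    records = None
    ssr_table = None
    leaves = None

    # --- load external inputs when synthesis is disabled -------------------
    if not enabled["synth"]:
        for key in ("traits", "ssr", "leaves"):
            path = config.inputs.get(key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input {key!r} not found: {path}")
        if config.inputs.get("traits"):
            records = pd.read_csv(config.inputs["traits"])
        if config.inputs.get("ssr"):
            ssr_table = pd.read_csv(config.inputs["ssr"], dtype=str).fillna("")
        if config.inputs.get("leaves"):
            leaves = pd.read_csv(config.inputs["leaves"])

    if enabled["synth"]:
        t = time.time()
        design = DesignSpec(seed=config.seed, **config.design)
        model = default_trait_model()
        records = generate_greenhouse(design, model)
        _write_csv(records, outdir / "traits.csv", manifest)
        ssr_table = generate_ssr(seed=config.seed,
                                 **{"n_samples": 79, **config.ssr_synth})
        _write_csv(ssr_table, outdir / "ssr.csv", manifest)
        leaves = generate_leaves(seed=config.seed)
        _write_csv(leaves, outdir / "leaves.csv", manifest)
        manifest["counts"]["pots_generated"] = int(len(records))
        manifest["counts"]["pots_analyzed"] = int(records["survived"].sum())
        manifest["counts"]["ssr_samples"] = int(len(ssr_table))
        log.info("synth: %d pots (%d surviving), %d SSR samples [%.2fs]",
                 len(records), records["survived"].sum(), len(ssr_table),
                 time.time() - t)

    if enabled["ssr"]:
        if ssr_table is None:
            raise ValueError("ssr stage needs an SSR table (enable synth or "
                             "provide inputs.ssr)")
        t = time.time()
        gt = call_multilocus_genotypes(ssr_table)
        _write_csv(gt.summary.reset_index(), outdir / "genotype_table.csv", manifest)
        freq_frames = []
        for locus in locus_columns(ssr_table):
            ft = frequency_table(ssr_table, locus)
            ft.insert(0, "locus", locus)
            freq_frames.append(ft)
        _write_csv(pd.concat(freq_frames, ignore_index=True),
                   outdir / "locus_frequencies.csv", manifest)
        d = dissimilarity_matrix(gt.to_frame())
        _write_csv(d, outdir / "genotype_dissimilarity.csv", manifest, index=True)
        counts = gt.summary["count"].to_dict()
        msn = minimum_spanning_network(d, node_sizes=counts)
        msn.write_graphml(outdir / "msn.graphml")
        manifest["outputs"].append("msn.graphml")
        msn.write_edgelist(outdir / "msn_edges.csv")
        manifest["outputs"].append("msn_edges.csv")
        manifest["counts"]["genotypes"] = int(gt.n_genotypes)
        manifest["counts"]["distinct_alleles"] = int(gt.n_distinct_alleles)
        manifest["counts"]["modal_genotype_alleles"] = int(gt.modal_allele_count)
        log.info("ssr: %d genotypes among %d samples [%.2fs]",
                 gt.n_genotypes, len(ssr_table), time.time() - t)

    completed = None
    survivors = None
    if enabled["impute"]:
        if records is None:
            raise ValueError("impute stage needs a trait table")
        t = time.time()
        survivors = records[records["survived"]].reset_index(drop=True)
        if len(survivors) == 0:
            raise ValueError("no surviving pots; nothing to analyze")
        imputer = IterativePCAImputer(**config.impute_params)
        completed = imputer.fit_transform(survivors[list(FUNCTIONAL_TRAITS)])
        out = pd.concat([survivors[["pot_id", "individual", "cytotype",
                                    "water", "co2"]], completed], axis=1)
        _write_csv(out, outdir / "traits_imputed.csv", manifest)
        manifest["counts"]["imputed_cells"] = int(
            survivors[list(FUNCTIONAL_TRAITS)].isna().sum().sum())
        log.info("impute: %d cells completed in %d iterations [%.2fs]",
                 manifest["counts"]["imputed_cells"], imputer.n_iter_,
                 time.time() - t)

    scape = None
    if enabled["scape"]:
        if completed is None:
            raise ValueError("scape stage needs imputed traits (enable impute)")
        t = time.time()
        scape = TraitScapePCA(**config.pca).fit(completed)
        _write_csv(pd.concat([survivors[["pot_id", "individual", "cytotype",
                                         "water", "co2"]],
                              scape.scores_], axis=1),
                   outdir / "scape_scores.csv", manifest)
        _write_csv(scape.loadings_.rename_axis("trait").reset_index(),
                   outdir / "scape_loadings.csv", manifest)
        _write_csv(pd.DataFrame({
            "dimension": [f"CV{i + 1}" for i in range(scape.n_components_)],
            "explained_variance_ratio": scape.explained_variance_ratio_}),
            outdir / "scape_explained_variance.csv", manifest)
        manifest["counts"]["scape_dimensions"] = int(scape.n_components_)
        log.info("scape: dim1+dim2 explain %.1f%% [%.2fs]",
                 100 * scape.explained_variance_ratio_[:2].sum(), time.time() - t)
        if config.figures:
            from .plots import trait_scape_biplot
            groups = (survivors["individual"].astype(str) + " "
                      + survivors["water"] + "/" + survivors["co2"])
            trait_scape_biplot(scape, groups, outdir / "trait_scape.svg")
            manifest["outputs"].append("trait_scape.svg")

    if enabled["plasticity"]:
        if scape is None:
            raise ValueError("plasticity stage needs a fitted trait-scape")
        t = time.time()
        full = pd.concat([survivors[["pot_id", "individual", "cytotype",
                                     "water", "co2"]], completed], axis=1)
        full["survived"] = True
        for group_by in ("individual", "cytotype"):
            res = plasticity_by_contrast(scape, full, group_by=group_by)
            _write_csv(res.ed_pairs, outdir / f"ed_pairs_{group_by}.csv", manifest)
            _write_csv(res.indices, outdir / f"mvpi_{group_by}.csv", manifest)
        amb = ambient_scores_by_individual(scape, full)
        tvi = trait_variation_index(amb)
        _write_csv(pd.DataFrame({"individual": list(tvi),
                                 "trait_variation": list(tvi.values())}),
                   outdir / "trait_variation.csv", manifest)
        # one-way comparisons of the indices
        try:
            per_ind = {ind: np.linalg.norm(rows - np.vstack(list(amb.values()))
                                           .mean(axis=0), axis=1)
                       for ind, rows in amb.items()}
            tvi_anova = one_way_anova(per_ind)
            _write_csv(tvi_anova.table.rename_axis("term").reset_index(),
                       outdir / "trait_variation_anova.csv", manifest)
        except ValueError as exc:
            log.warning("trait-variation ANOVA skipped: %s", exc)
        res_ind = plasticity_by_contrast(scape, full, group_by="individual")
        merged = res_ind.indices.merge(
            full[["individual", "cytotype"]].drop_duplicates(),
            left_on="group", right_on="individual")
        cyto_groups = {c: g["mvpi"].dropna().to_numpy()
                       for c, g in merged.groupby("cytotype")}
        try:
            mvpi_anova = one_way_anova(cyto_groups)
            _write_csv(mvpi_anova.table.rename_axis("term").reset_index(),
                       outdir / "mvpi_anova.csv", manifest)
        except ValueError as exc:
            log.warning("MVPi ANOVA skipped: %s", exc)
        log.info("plasticity: indices for %d individuals [%.2fs]",
                 len(tvi), time.time() - t)
        if config.figures:
            from .plots import index_bars
            index_bars(res_ind.indices, path=outdir / "mvpi_bars.svg")
            manifest["outputs"].append("mvpi_bars.svg")

    if enabled["anova"]:
        if records is None:
            raise ValueError("anova stage needs a trait table")
        t = time.time()
        responses = config.anova.get("responses", list(ALL_TRAITS))
        use_boxcox = config.anova.get("boxcox", True)
        tables, checks, hsd_frames = [], [], []
        for response in responses:
            res = factorial_anova(records, response,
                                  transform="boxcox" if use_boxcox else None)
            tab = res.table.rename_axis("term").reset_index()
            tab.insert(0, "response", response)
            if res.transform is not None:
                tab["boxcox_lambda"] = res.transform.lmbda
            tables.append(tab)
            checks.append({"response": response, **res.assumptions})
            if res.posthoc is not None:
                ph = res.posthoc.copy()
                ph.insert(0, "response", response)
                hsd_frames.append(ph)
        _write_csv(pd.concat(tables, ignore_index=True),
                   outdir / "anova_tables.csv", manifest)
        _write_csv(pd.DataFrame(checks), outdir / "anova_assumptions.csv", manifest)
        if hsd_frames:
            _write_csv(pd.concat(hsd_frames, ignore_index=True),
                       outdir / "tukey_hsd.csv", manifest)
        manifest["counts"]["anova_responses"] = len(responses)
        log.info("anova: %d responses [%.2fs]", len(responses), time.time() - t)
        if config.figures:
            from .plots import interaction_plot
            for response in responses[:3]:
                interaction_plot(records, response,
                                 outdir / f"interaction_{response}.svg")
                manifest["outputs"].append(f"interaction_{response}.svg")

    if enabled["allometry"]:
        if leaves is None:
            raise ValueError("allometry stage needs a leaf table")
        t = time.time()
        model = fit_leaf_area(leaves)
        model.to_json(outdir / "leaf_area_model.json")
        manifest["outputs"].append("leaf_area_model.json")
        manifest["counts"]["leaves"] = int(len(leaves))
        log.info("allometry: slope %.5f intercept %.2f R2 %.4f (reference "
                 "slope %.5f) [%.2fs]", model.slope_, model.intercept_,
                 model.r_squared_, reference_model().slope_, time.time() - t)

    manifest["runtime_s"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
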