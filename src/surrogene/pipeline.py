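"""End-to-end pipeline: inputs -> profiles -> surrogate calls -> associations.

A :class:`RunConfig` names the input files and the analysis parameters;
:func:`run_pipeline` executes the stages in order, writes every output
table, and records a manifest (config echo, seed, package version, SHA-256
input checksums) so a run can be reproduced and input drift detected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    SurvivalDataset,
    discretize_gi50,
    fit_drug_classifier,
    fit_survival_tree,
    logrank_test,
    subtype_association,
)
from .core import call_surrogates, calls_to_table, expand_seed_set
from .genomic import build_profiles, read_gistic, read_maf
from .network import load_network

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (YAML-loadable)."""

    network: str
    maf: str
    gistic: str
    seeds: str
    out_dir: str
    gi50: str | None = None
    subtypes: str | None = None
    clinical: str | None = None
    node_list: str | None = None
    alpha: float = 0.05
    n_perm: int = 10_000
    mode: str = "exact"
    min_connections: int = 2
    amp_threshold: int = 2
    del_threshold: int = -2
    exclude_classes: list[str] = field(default_factory=lambda: ["Silent"])
    max_leaves: int = 4
    min_leaf: int = 10
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("network", "maf", "gistic", "seeds", "gi50", "subtypes", "clinical", "node_list"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.mode not in ("exact", "perm"):
            raise ValueError(f"mode must be 'exact' or 'perm', got {self.mode!r}")
        if self.mode == "perm" and self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 in permutation mode")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow; returns the paths of every artifact written."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc

    net = stage("load_network", load_network, config.network, config.node_list)
    maf_sets = stage("read_maf", read_maf, config.maf, set(config.exclude_classes))
    cn_sets = stage(
        "read_gistic", read_gistic, config.gistic, config.amp_threshold, config.del_threshold
    )
    profiles = stage("build_profiles", build_profiles, maf_sets, cn_sets, net)

    with open(config.seeds) as fh:
        seed_genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    gene_set = stage("expand_seed_set", expand_seed_set, net, seed_genes, config.min_connections)

    calls, matrix = stage(
        "call_surrogates",
        call_surrogates,
        net,
        gene_set,
        profiles,
        config.alpha,
        config.mode,
        config.n_perm,
        config.rng_seed,
    )

    artifacts["calls"] = out / "calls.csv"
    calls_to_table(calls).to_csv(artifacts["calls"], index=False)
    artifacts["matrix"] = out / "matrix.csv"
    matrix.to_csv(artifacts["matrix"])

    per_sample = calls_to_table(calls).groupby("sample")["significant"].sum()
    logger.info(
        "mean significant surrogates per sample: %.2f over %d samples",
        per_sample.mean(),
        len(per_sample),
    )

    features = matrix.significant()

    if config.gi50 is not None:
        gi50 = pd.read_csv(config.gi50, index_col="sample")
        reports = []
        for drug in gi50.columns:
            col = gi50[drug].reindex(features.index)
            labels = stage("discretize_gi50", discretize_gi50, col)
            try:
                rep = stage(
                    "fit_drug_classifier",
                    fit_drug_classifier,
                    features,
                    labels,
                    config.rng_seed,
                    drug=drug,
                )
            except PipelineError as err:
                logger.warning("drug %s skipped: %s", drug, err.cause)
                continue
            reports.append(
                (drug, rep.oob_error_initial, rep.oob_error_refined, ";".join(rep.features_refined))
            )
        artifacts["drug_report"] = out / "drug_report.csv"
        pd.DataFrame(
            reports, columns=["drug", "oob_error_initial", "oob_error_refined", "features_refined"]
        ).to_csv(artifacts["drug_report"], index=False)

    if config.subtypes is not None:
        subt = pd.read_csv(config.subtypes)
        labels = dict(zip(subt["sample"].astype(str), subt["subtype"].astype(str)))
        assoc = stage("subtype_association", subtype_association, matrix, labels)
        artifacts["subtype_association"] = out / "subtype_association.csv"
        assoc.to_csv(artifacts["subtype_association"], index=False)

    if config.clinical is not None:
        clin = pd.read_csv(config.clinical).set_index("sample")
        common = [s for s in features.index if s in clin.index]
        data = SurvivalDataset(
            features=features.loc[common],
            time=clin.loc[common, "time"],
            event=clin.loc[common, "event"].astype(int),
        )
        tree = stage(
            "fit_survival_tree", fit_survival_tree, data, config.max_leaves, config.min_leaf
        )
        artifacts["survival_tree"] = out / "survival_tree.txt"
        artifacts["survival_groups"] = out / "survival_groups.csv"
        with open(artifacts["survival_tree"], "w") as fh:
            fh.write(tree.render() + "\n")
            if tree.logrank_p is not None:
                fh.write(
                    f"logrank_statistic\t{tree.logrank_statistic:.6g}\n"
                    f"logrank_p\t{tree.logrank_p:.6g}\n"
                )
        groups = tree.assign(data.features)
        groups.to_csv(artifacts["survival_groups"], index_label="sample")

    manifest = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "rng_seed": config.rng_seed,
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("network", "maf", "gistic", "seeds", "gi50", "subtypes", "clinical")
            if getattr(config, name) is not None
        },
        "n_samples": len(profiles),
        "n_surrogate_genes": len(gene_set.expanded),
        "mean_significant_per_sample": float(per_sample.mean()),
    }
    artifacts["manifest"] = out / "manifest.json"
    with open(artifacts["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return artifacts
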