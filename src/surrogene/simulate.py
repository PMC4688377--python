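"""Synthetic cohorts with planted neighborhood-enrichment signal.

The generator emulates the full input stack — a scale-free interaction
network, per-sample somatic alteration profiles, and phenotypes (drug
response, subtype, survival) tied to the planted signal — in the exact file
formats the I/O layer reads, so every stage of the pipeline is testable
with known ground truth.

The planted signal is *neighbor* enrichment, not self-mutation of the
target: each sample alters each gene independently at ``background_rate``,
except that neighbors of a planted target are altered with probability
``min(1, enrichment x background_rate)``.  That is precisely the structure
the neighborhood statistic is built to detect, while the targets themselves
stay at background rate.  Note a consequence: planting enrichment also
raises the per-sample alteration count M, and since the null conditions on
M, realized detection power is lower than a naive ``enrichment x
background`` argument suggests (see docs/methods.md).

Alterations are typed as ~30% copy-number (split evenly into gains and
losses) and ~70% point mutations, mirroring the CNA share seen in cell-line
cohorts; the proportion is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import exact_tail_pvalue
from .genomic import AlterationProfile
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedTruth",
    "SyntheticCohort",
    "generate_network",
    "generate_cohort",
    "generate_phenotypes",
    "write_fixture",
]


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic cohort."""

    targets: list[tuple[str, float]]  # (gene, enrichment factor)
    background_rate: float
    exposed_samples: list[str]  # samples carrying the planted enrichment

    @property
    def target_genes(self) -> list[str]:
        return [g for g, _ in self.targets]


@dataclass
class SyntheticCohort:
    net: PPINetwork
    profiles: list[AlterationProfile]
    truth: PlantedTruth
    rng_seed: int
    gi50: pd.DataFrame | None = None  # samples x drugs
    subtypes: dict[str, str] | None = None
    clinical: pd.DataFrame | None = None  # sample, time, event

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def surrogate_positive(self, alpha: float = 0.05) -> pd.Series:
        """Per-sample indicator: any planted target significant (exact test).

        Deterministic given the profiles; this is the latent group label the
        phenotype generators condition on.
        """
        N = self.net.n_nodes
        out = {}
        for prof in self.profiles:
            hit = False
            for gene in self.truth.target_genes:
                x = len(self.net.neighbors(gene) & prof.altered)
                p = exact_tail_pvalue(N, self.net.degree(gene), prof.M, x)
                if p < alpha:
                    hit = True
                    break
            out[prof.sample_id] = int(hit)
        return pd.Series(out, name="surrogate_positive")


def generate_network(
    n_nodes: int,
    model: str = "scale_free",
    param: float = 3,
    rng_seed: int | None = None,
) -> PPINetwork:
    """Random simple undirected gene network.

    ``scale_free`` uses Barabasi-Albert preferential attachment (*param* =
    edges per new node), giving the heavy-tailed degree distribution typical
    of curated interactomes; ``erdos_renyi`` uses G(n, p) with *param* = p.
    Nodes are labeled G0000, G0001, ...
    """
    if n_nodes < 10:
        raise ValueError(f"need n_nodes >= 10, got {n_nodes}")
    if model == "scale_free":
        g = nx.barabasi_albert_graph(n_nodes, int(param), seed=rng_seed)
    elif model == "erdos_renyi":
        g = nx.gnp_random_graph(n_nodes, float(param), seed=rng_seed)
    else:
        raise ValueError(f"unknown network model: {model!r}")
    mapping = {i: f"G{i:04d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    return PPINetwork(graph=g)


def pick_targets(
    net: PPINetwork,
    n_targets: int,
    enrichment: float,
    min_degree: int = 20,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, float]]:
    """Default target choice: the *n_targets* best-connected genes.

    Oncogenes sit among the hubs of the interactome, and the neighborhood
    statistic is best powered for well-connected genes, so the default
    plants signal on the highest-degree nodes (requiring degree >=
    *min_degree*).
    """
    table = net.degree_table().sort_values(["degree", "gene"], ascending=[False, True])
    eligible = table[table["degree"] >= min_degree]
    if len(eligible) < n_targets:
        raise ValueError(
            f"only {len(eligible)} genes with degree >= {min_degree}; "
            f"cannot plant {n_targets} targets"
        )
    return [(g, float(enrichment)) for g in eligible["gene"].head(n_targets)]


def generate_cohort(
    net: PPINetwork,
    n_samples: int,
    background_rate: float,
    targets: Sequence[tuple[str, float]],
    rng_seed: int,
    cna_fraction: float = 0.30,
    exposed_fraction: float = 1.0,
) -> SyntheticCohort:
    """Simulate per-sample alteration profiles with planted neighbor enrichment.

    Every gene is altered independently at *background_rate*; in "exposed"
    samples (a seeded random fraction *exposed_fraction*, default all),
    neighbors of each planted target are altered at ``min(1, enrichment x
    background_rate)`` instead (a gene neighboring several targets takes the
    maximum).  Each altered gene is typed as copy-number with probability
    *cna_fraction* (gain or loss equally) and as a point mutation otherwise.
    """
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background_rate must be in (0, 1)")
    for gene, enr in targets:
        if gene not in net:
            raise ValueError(f"target gene not in network: {gene!r}")
        if enr < 1.0:
            raise ValueError(f"enrichment factor must be >= 1, got {enr}")
        if enr * background_rate > 1.0:
            logger.warning(
                "target %s: enrichment x background = %.3f clipped at 1",
                gene,
                enr * background_rate,
            )
    rng = np.random.default_rng(rng_seed)
    nodes = net.node_order()
    N = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}

    base = np.full(N, background_rate)
    enriched = base.copy()
    for gene, enr in targets:
        p = min(1.0, enr * background_rate)
        for nbr in net.neighbors(gene):
            enriched[idx[nbr]] = max(enriched[idx[nbr]], p)

    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    n_exposed = int(round(exposed_fraction * n_samples))
    exposed = set(rng.choice(n_samples, size=n_exposed, replace=False).tolist())

    profiles = []
    for j, sid in enumerate(sample_ids):
        prob = enriched if j in exposed else base
        altered = rng.random(N) < prob
        is_cna = rng.random(N) < cna_fraction
        is_gain = rng.random(N) < 0.5
        mutated, gained, lost = set(), set(), set()
        for i in np.flatnonzero(altered):
            if is_cna[i]:
                (gained if is_gain[i] else lost).add(nodes[i])
            else:
                mutated.add(nodes[i])
        profiles.append(
            AlterationProfile(sample_id=sid, mutated=mutated, gained=gained, lost=lost)
        )
    truth = PlantedTruth(
        targets=list(targets),
        background_rate=background_rate,
        exposed_samples=[sample_ids[j] for j in sorted(exposed)],
    )
    return SyntheticCohort(net=net, profiles=profiles, truth=truth, rng_seed=rng_seed)


def generate_phenotypes(
    cohort: SyntheticCohort,
    rng_seed: int,
    drug_effect: float = 2.0,
    n_drugs: int = 3,
    noise_sd: float = 0.5,
    subtype_rule: Callable[[int], str] | None = None,
    subtype_flip_prob: float = 0.1,
    survival_hr: Mapping[str, float] | None = None,
    baseline_hazard: float = 0.1,
    censoring_rate: float = 0.2,
    alpha: float = 0.05,
) -> SyntheticCohort:
    """Attach drug response, subtype and survival tied to the planted signal.

    The latent group is ``surrogate_positive``: whether the sample carries a
    significant planted surrogate (exact test at *alpha*).  Then

    * GI50 = 1.0 + drug_effect x 1[surrogate-negative] + N(0, noise_sd) —
      surrogate-positive samples are the *sensitive* (low-GI50) class;
    * subtype = rule(surrogate_positive) with label noise
      *subtype_flip_prob* (default rule: positive -> "basal", else
      "luminal");
    * survival time ~ Exponential(baseline_hazard x HR(group)), with
      HR taken from *survival_hr* (default {"positive": 4.0}); a seeded
      fraction *censoring_rate* of subjects is censored uniformly before
      their event time.
    """
    rng = np.random.default_rng(rng_seed)
    positive = cohort.surrogate_positive(alpha=alpha)
    samples = cohort.sample_ids
    pos = positive.loc[samples].to_numpy()

    # drug response
    gi50 = pd.DataFrame(index=samples)
    for d in range(n_drugs):
        vals = 1.0 + drug_effect * (1 - pos) + rng.normal(0.0, noise_sd, len(samples))
        gi50[f"drug_{d}"] = vals

    # subtype
    if subtype_rule is None:
        subtype_rule = lambda flag: "basal" if flag else "luminal"
    subtypes = {}
    labels = sorted({subtype_rule(0), subtype_rule(1)})
    for sid, flag in zip(samples, pos):
        lab = subtype_rule(int(flag))
        if rng.random() < subtype_flip_prob and len(labels) > 1:
            lab = labels[1 - labels.index(lab)] if lab in labels else lab
        subtypes[sid] = lab

    # survival
    hr_map = dict(survival_hr) if survival_hr is not None else {"positive": 4.0}
    hr_pos = float(hr_map.get("positive", hr_map.get("exposed", 4.0)))
    hazard = baseline_hazard * np.where(pos == 1, hr_pos, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    censor = rng.random(len(samples)) < censoring_rate
    u = rng.random(len(samples))
    time = np.where(censor, t_event * u, t_event)
    event = (~censor).astype(int)
    clinical = pd.DataFrame({"sample": samples, "time": time, "event": event})

    cohort.gi50 = gi50
    cohort.subtypes = subtypes
    cohort.clinical = clinical
    return cohort


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the formats the I/O layer reads.

    Produces edges.tsv, muts.maf, cn.tsv, seeds.txt (the planted targets),
    and — when phenotypes were generated — gi50.csv, subtypes.csv,
    clinical.csv.  Reading the files back reproduces the profiles exactly;
    the GISTIC matrix carries every sample as a column, so samples with no
    mutations survive the round trip.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["network"] = out / "edges.tsv"
    with open(paths["network"], "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in cohort.net.graph.edges):
            fh.write(f"{a}\t{b}\n")

    paths["maf"] = out / "muts.maf"
    with open(paths["maf"], "w") as fh:
        fh.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n")
        for prof in cohort.profiles:
            for gene in sorted(prof.mutated):
                fh.write(f"{gene}\t{prof.sample_id}\tMissense_Mutation\n")

    paths["gistic"] = out / "cn.tsv"
    samples = cohort.sample_ids
    nodes = cohort.net.node_order()
    with open(paths["gistic"], "w") as fh:
        fh.write("Gene Symbol\t" + "\t".join(samples) + "\n")
        for gene in nodes:
            calls = []
            for prof in cohort.profiles:
                if gene in prof.gained:
                    calls.append("2")
                elif gene in prof.lost:
                    calls.append("-2")
                else:
                    calls.append("0")
            fh.write(gene + "\t" + "\t".join(calls) + "\n")

    paths["seeds"] = out / "seeds.txt"
    with open(paths["seeds"], "w") as fh:
        fh.writelines(f"{g}\n" for g in cohort.truth.target_genes)

    paths["gi50"] = out / "gi50.csv"
    gi50 = cohort.gi50 if cohort.gi50 is not None else pd.DataFrame(index=pd.Index([], name="sample"))
    gi50.to_csv(paths["gi50"], index_label="sample")

    paths["subtypes"] = out / "subtypes.csv"
    subt = pd.DataFrame(
        sorted((cohort.subtypes or {}).items()), columns=["sample", "subtype"]
    )
    subt.to_csv(paths["subtypes"], index=False)

    paths["clinical"] = out / "clinical.csv"
    clin = (
        cohort.clinical
        if cohort.clinical is not None
        else pd.DataFrame(columns=["sample", "time", "event"])
    )
    clin.to_csv(paths["clinical"], index=False)

    logger.info("wrote fixture set to %s", out)
    return paths
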