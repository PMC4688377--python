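"""Parse somatic alteration inputs into per-sample profiles.

Two standard tabular formats are consumed:

* **MAF** (Mutation Annotation Format): one somatic variant per row, with at
  least ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
  ``Variant_Classification`` columns.  Silent variants are excluded by
  default; the filter is configurable.
* **GISTIC thresholded-by-genes**: genes x samples integer matrix with calls
  in {-2, -1, 0, 1, 2}.  A call >= ``amp_threshold`` marks a copy-number
  gain, <= ``del_threshold`` a loss (defaults +/-2, i.e. high-confidence
  amplifications/deletions).

The merged unit is an :class:`AlterationProfile`: the distinct mutated,
gained and lost genes of one sample, restricted to the nodes of the active
PPI network.  The per-sample alteration count ``M`` counts **distinct
altered genes**, not events — a gene mutated twice, or both mutated and
amplified, contributes one.  ``M`` parameterizes the permutation null, which
places M distinct alterations on the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationProfile",
    "read_maf",
    "read_gistic",
    "build_profiles",
    "profiles_to_table",
]

DEFAULT_EXCLUDE_CLASSES = frozenset({"Silent"})

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


class GenomicFormatError(ValueError):
    """Raised for malformed MAF / GISTIC inputs."""


@dataclass
class AlterationProfile:
    """Distinct altered genes of one sample, restricted to the network."""

    sample_id: str
    mutated: set[str] = field(default_factory=set)
    gained: set[str] = field(default_factory=set)
    lost: set[str] = field(default_factory=set)

    @property
    def altered(self) -> set[str]:
        return self.mutated | self.gained | self.lost

    @property
    def M(self) -> int:
        """Number of distinct altered genes (the null's draw size)."""
        return len(self.altered)

    def alteration_types(self, gene: str) -> tuple[str, ...]:
        """Which of mutation / gain / loss affect *gene* in this sample."""
        types = []
        if gene in self.mutated:
            types.append("mutation")
        if gene in self.gained:
            types.append("gain")
        if gene in self.lost:
            types.append("loss")
        return tuple(types)


def read_maf(
    path: str | Path,
    exclude_classes: Iterable[str] = DEFAULT_EXCLUDE_CLASSES,
) -> dict[str, set[str]]:
    """Read a MAF file into per-sample distinct mutated gene sets.

    Rows whose ``Variant_Classification`` is in *exclude_classes* (default:
    {"Silent"}) are dropped, but their samples remain present with possibly
    empty sets, so a fully-silent sample still appears in the cohort.
    """
    exclude = set(exclude_classes)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in MAF_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise GenomicFormatError(f"MAF {path} missing required column {col!r}")
    out: dict[str, set[str]] = {str(s): set() for s in df["Tumor_Sample_Barcode"]}
    keep = ~df["Variant_Classification"].isin(exclude)
    for sample, gene in zip(
        df.loc[keep, "Tumor_Sample_Barcode"], df.loc[keep, "Hugo_Symbol"]
    ):
        out[str(sample)].add(str(gene).strip().upper())
    logger.info(
        "read %d MAF rows (%d kept, %d excluded by class) for %d sample(s)",
        len(df),
        int(keep.sum()),
        int((~keep).sum()),
        len(out),
    )
    return out


def read_gistic(
    path: str | Path,
    amp_threshold: int = 2,
    del_threshold: int = -2,
    gene_filter: Iterable[str] | None = None,
) -> dict[str, tuple[set[str], set[str]]]:
    """Read a GISTIC thresholded-by-genes matrix.

    Returns per sample a ``(gained, lost)`` pair:  gained iff call >=
    *amp_threshold*, lost iff call <= *del_threshold*.  Annotation columns
    other than the gene-symbol column (``Locus ID``, ``Cytoband``) are
    ignored.  *gene_filter* optionally restricts calls to a gene list (e.g.
    genes in high-confidence peaks).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col = None
    for cand in ("Gene Symbol", "Gene_Symbol", "Hugo_Symbol", df.columns[0]):
        if cand in df.columns:
            gene_col = cand
            break
    genes = df[gene_col].astype(str).str.strip().str.upper()
    skip = {gene_col, "Locus ID", "Locus_ID", "Cytoband"}
    sample_cols = [c for c in df.columns if c not in skip]
    calls = pd.DataFrame(index=genes.values)
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise GenomicFormatError(
                f"non-numeric copy-number call at row {row + 2}, column {col!r} "
                f"in {path}: {df[col][numeric.isna()].iloc[0]!r}"
            )
        calls[col] = numeric.values
    allowed = None if gene_filter is None else {g.strip().upper() for g in gene_filter}
    out: dict[str, tuple[set[str], set[str]]] = {}
    for col in sample_cols:
        vals = calls[col]
        gained = set(calls.index[vals >= amp_threshold])
        lost = set(calls.index[vals <= del_threshold])
        if allowed is not None:
            gained &= allowed
            lost &= allowed
        out[str(col)] = (gained, lost)
    logger.info(
        "read GISTIC matrix %s: %d genes x %d samples", path, len(calls), len(out)
    )
    return out


def build_profiles(
    maf_sets: Mapping[str, set[str]] | None,
    cn_sets: Mapping[str, tuple[set[str], set[str]]] | None,
    net: PPINetwork,
    sample_ids: Iterable[str] | None = None,
) -> list[AlterationProfile]:
    """Merge mutation and copy-number gene sets into network-restricted profiles.

    Samples present in only one source get empty sets for the other.  Genes
    absent from the network are dropped (counted per sample in the log):
    only network genes can participate in the neighborhood statistic or in
    the null, keeping the observed count and the null distribution on the
    same gene universe.
    """
    maf_sets = maf_sets or {}
    cn_sets = cn_sets or {}
    if sample_ids is None:
        sample_ids = sorted(set(maf_sets) | set(cn_sets))
    nodes = net.nodes
    profiles = []
    for sid in sample_ids:
        mutated = set(maf_sets.get(sid, set()))
        gained, lost = cn_sets.get(sid, (set(), set()))
        n_outside = len((mutated | gained | lost) - nodes)
        prof = AlterationProfile(
            sample_id=sid,
            mutated=mutated & nodes,
            gained=set(gained) & nodes,
            lost=set(lost) & nodes,
        )
        if n_outside:
            logger.info(
                "sample %s: dropped %d altered gene(s) absent from network",
                sid,
                n_outside,
            )
        profiles.append(prof)
    return profiles


def profiles_to_table(profiles: Iterable[AlterationProfile]) -> pd.DataFrame:
    """Long-format summary: one row per (sample, gene, alteration type)."""
    rows = []
    for p in profiles:
        for gene in sorted(p.altered):
            for typ in p.alteration_types(gene):
                rows.append((p.sample_id, gene, typ))
    return pd.DataFrame(rows, columns=["sample", "gene", "type"])
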