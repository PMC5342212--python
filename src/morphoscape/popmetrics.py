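"""Population-level morphometric and genetic statistics.

Aggregates inter-individual distance matrices to inter-population means
(mD-style construction, shared by shape, size and genetic distances),
computes within-population mean pairwise diversity (md), mean wing size
(wsM), covariate difference matrices, multi-locus sequence mismatch
distances (IID2-style) and per-population nucleotide diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationAssignment",
    "LocusAlignmentSet",
    "aggregate_between_populations",
    "within_population_diversity",
    "pairwise_absolute_difference",
    "population_mean_size",
    "sequence_mismatch_matrix",
    "nucleotide_diversity",
    "read_locus_fasta_dir",
    "build_population_table",
]

_VALID_BASES = frozenset("ACGT")


@dataclass
class PopulationAssignment:
    """Mapping from individual id to population id."""

    mapping: dict[str, str]

    def populations(self) -> list[str]:
        """Population ids in first-appearance order."""
        seen: list[str] = []
        for p in self.mapping.values():
            if p not in seen:
                seen.append(p)
        return seen

    def members(self, population_id: str) -> list[str]:
        return [i for i, p in self.mapping.items() if p == population_id]

    def sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.mapping.values():
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def check_covers(self, labels: Sequence[str]) -> None:
        missing = [l for l in labels if l not in self.mapping]
        if missing:
            raise ValueError(f"individuals without population assignment: {missing}")


@dataclass
class LocusAlignmentSet:
    """Per-locus aligned haploid sequences keyed by individual id.

    ``loci`` maps locus name to {individual_id: sequence}; all sequences
    within a locus must have equal length, over the alphabet {A,C,G,T,N,-}.
    """

    loci: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for name, seqs in self.loci.items():
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                raise ValueError(
                    f"locus {name!r}: unequal sequence lengths {sorted(lengths)}"
                )
        self.loci = {
            name: {i: s.upper() for i, s in seqs.items()}
            for name, seqs in self.loci.items()
        }

    def individuals(self) -> list[str]:
        ids: list[str] = []
        for seqs in self.loci.values():
            for i in seqs:
                if i not in ids:
                    ids.append(i)
        return ids


def aggregate_between_populations(
    d: DistanceMatrix, pops: PopulationAssignment
) -> DistanceMatrix:
    """Mean inter-individual distance between each pair of populations.

    mD(j1, j2) = (1 / (n_j1 * n_j2)) * sum over cross-population pairs of
    d(i1, i2).  The same construction serves shape (mD), size (wsD) and
    genetic (IID2) inter-population matrices.
    """
    pops.check_covers(d.labels)
    pop_ids = pops.populations()
    idx = {
        p: np.array([d.index_of(i) for i in pops.members(p) if i in d.labels])
        for p in pop_ids
    }
    pop_ids = [p for p in pop_ids if len(idx[p]) > 0]
    m = len(pop_ids)
    if m < 2:
        raise ValueError("need at least 2 populations to aggregate")
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            block = d.values[np.ix_(idx[pop_ids[a]], idx[pop_ids[b]])]
            out[a, b] = out[b, a] = block.mean()
    return DistanceMatrix(pop_ids, out, f"mean_{d.metric_name}")


def within_population_diversity(
    d: DistanceMatrix, pops: PopulationAssignment
) -> dict[str, float]:
    """Mean pairwise distance within each population (md).

    md(j) = (2 / (n_j (n_j - 1))) * sum over unordered within-population
    pairs.  Populations with fewer than 2 members are excluded.
    """
    pops.check_covers(d.labels)
    result: dict[str, float] = {}
    for p in pops.populations():
        members = [i for i in pops.members(p) if i in d.labels]
        if len(members) < 2:
            continue
        idx = np.array([d.index_of(i) for i in members])
        block = d.values[np.ix_(idx, idx)]
        n = len(idx)
        result[p] = float(block[np.triu_indices(n, k=1)].mean())
    return result


def pairwise_absolute_difference(
    values: Mapping[str, float], metric_name: str = "abs_difference"
) -> DistanceMatrix:
    """|v_i - v_j| matrix over the given units."""
    labels = list(values.keys())
    if len(labels) < 2:
        raise ValueError("need at least 2 units")
    missing = [l for l in labels if values[l] is None or not np.isfinite(values[l])]
    if missing:
        raise ValueError(f"missing values for units: {missing}")
    v = np.array([values[l] for l in labels], dtype=float)
    return DistanceMatrix(labels, np.abs(v[:, None] - v[None, :]), metric_name)


def population_mean_size(
    cs: Mapping[str, float], pops: PopulationAssignment
) -> dict[str, float]:
    """Arithmetic mean centroid size per population (wsM)."""
    pops.check_covers(list(cs.keys()))
    result: dict[str, float] = {}
    for p in pops.populations():
        members = [i for i in pops.members(p) if i in cs]
        if members:
            result[p] = float(np.mean([cs[i] for i in members]))
    return result


def _site_comparison(s1: str, s2: str) -> tuple[int, int]:
    """(differing sites, comparable sites) counting only A/C/G/T positions."""
    comparable = 0
    diffs = 0
    for a, b in zip(s1, s2):
        if a in _VALID_BASES and b in _VALID_BASES:
            comparable += 1
            if a != b:
                diffs += 1
    return diffs, comparable


def sequence_mismatch_matrix(seqs: LocusAlignmentSet) -> DistanceMatrix:
    """Per-site mismatch distance between individuals, averaged over loci.

    For each locus shared by a pair, distance = (sites where both bases are
    in {A,C,G,T} and differ) / (sites where both are in {A,C,G,T}); the
    pair's distance is the mean over its shared loci.  Gaps and Ns are
    excluded pairwise; loci with zero comparable sites for a pair are
    skipped with a warning.
    """
    ids = seqs.individuals()
    n = len(ids)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            per_locus = []
            for name, locus in seqs.loci.items():
                if ids[a] not in locus or ids[b] not in locus:
                    continue
                diffs, comparable = _site_comparison(locus[ids[a]], locus[ids[b]])
                if comparable == 0:
                    logger.warning(
                        "locus %s: no comparable sites for pair (%s, %s); skipped",
                        name,
                        ids[a],
                        ids[b],
                    )
                    continue
                per_locus.append(diffs / comparable)
            if not per_locus:
                raise ValueError(
                    f"pair ({ids[a]}, {ids[b]}) shares no locus with comparable sites"
                )
            out[a, b] = out[b, a] = float(np.mean(per_locus))
    return DistanceMatrix(ids, out, "sequence_mismatch")


def nucleotide_diversity(
    seqs: LocusAlignmentSet, pops: PopulationAssignment
) -> dict[str, float]:
    """Per-population nucleotide diversity (per site), averaged over loci.

    Within each population and locus, the mean over unordered member pairs of
    (pairwise differences / comparable sites); the population value is the
    unweighted mean over loci with at least 2 sequenced members.  Populations
    never reaching that precondition are excluded.
    """
    result: dict[str, float] = {}
    for p in pops.populations():
        members = pops.members(p)
        per_locus: list[float] = []
        for name, locus in seqs.loci.items():
            present = [i for i in members if i in locus]
            if len(present) < 2:
                continue
            pair_values = []
            for a in range(len(present)):
                for b in range(a + 1, len(present)):
                    diffs, comparable = _site_comparison(
                        locus[present[a]], locus[present[b]]
                    )
                    if comparable > 0:
                        pair_values.append(diffs / comparable)
            if pair_values:
                per_locus.append(float(np.mean(pair_values)))
        if per_locus:
            result[p] = float(np.mean(per_locus))
    return result


def read_locus_fasta_dir(directory) -> LocusAlignmentSet:
    """Read one FASTA alignment per locus from a directory.

    Each ``*.fasta``/``*.fa`` file is one locus; record ids are individual
    ids.  Returns an empty set if the directory contains no FASTA files.
    """
    directory = Path(directory)
    loci: dict[str, dict[str, str]] = {}
    for path in sorted(directory.glob("*")):
        if path.suffix.lower() not in (".fasta", ".fa", ".fna"):
            continue
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if seqs:
            loci[path.stem] = seqs
    return LocusAlignmentSet(loci)


def build_population_table(
    pops: PopulationAssignment,
    coords: Mapping[str, tuple[float, float]],
    md: Mapping[str, float],
    wsm: Mapping[str, float],
    pi: Mapping[str, float],
    covariates: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Assemble the per-population table used for LR-CA and surfaces.

    ``coords`` maps population id to (longitude, latitude); ``covariates``
    maps covariate name to {population_id: value}.  md and pi are NaN where
    their sample-size preconditions fail.
    """
    pop_ids = pops.populations()
    sizes = pops.sizes()
    rows = []
    for p in pop_ids:
        row: dict[str, object] = {
            "population_id": p,
            "longitude": coords[p][0],
            "latitude": coords[p][1],
            "n": sizes[p],
            "md": md.get(p, np.nan),
            "wsM": wsm.get(p, np.nan),
            "pi": pi.get(p, np.nan),
        }
        for name, vals in covariates.items():
            row[name] = vals.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("population_id")
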