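"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the package is built around:
two tomato genotypes ("B" resistant, "C" susceptible) grown in two
native field soils ("AL" suppressive, "RO" conducive) and a disinfected
control substrate ("CONT"), three biological replicates each — 18
samples of 50 bp single-end host-targeted RNA-seq whose non-host reads
carry the root microbiota signal.  Every generator records its ground
truth so consuming tests can score accuracy, power and error rates
without re-simulation, and every generator draws from a single RNG
stream derived from (seed, generator name) so adding a generator never
perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pseudoreads import MappedInterval, ReferenceSet
from .read_assignment import AlignmentHit
from .taxonomy import TaxonomyNode, TaxonomyTree, NO_RANK

GENOTYPES = ("B", "C")
SOILS = ("AL", "RO", "CONT")

#: ranks used below the microbial kingdoms in the synthetic taxonomy
_SUB_KINGDOM_RANKS = ("phylum", "family", "genus", "species")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study, with defaults matching the design
    the pipeline targets.

    ``identity_noise_sd`` is the s.d. of simulated percent identities
    around 98%; reads whose identity falls below the 97% assignment
    threshold become unassignable, as in real data.  ``ambiguity_rate``
    is the probability that a read hits a sibling species at equal
    score, forcing LCA promotion to the genus.
    """

    seed: int = 0
    n_leaves: int = 24
    ranks: Sequence[str] = _SUB_KINGDOM_RANKS
    n_reads: int = 1000
    host_fraction: float = 0.0
    identity_noise_sd: float = 0.0
    ambiguity_rate: float = 0.0
    nb_dispersion: float = 0.2
    effect_size: float = 1.0
    affected_fraction: float = 0.3
    n_samples_per_group: int = 3
    n_features: int = 50

    def __post_init__(self):
        for name in ("host_fraction", "ambiguity_rate", "affected_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")


def _rng(cfg: SyntheticConfig, name: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, zlib.crc32(name.encode())])


# -- taxonomy ------------------------------------------------------------


def make_taxonomy(cfg: SyntheticConfig) -> TaxonomyTree:
    """Balanced ranked tree with microbial and contaminant clades.

    Structure: root -> superkingdoms Bacteria and Eukaryota; Eukaryota
    carries the kingdoms Fungi, Viridiplantae and Metazoa.  The
    ``cfg.n_leaves`` microbial species are split between Bacteria and
    Fungi and hang from balanced phylum/family/genus chains; the two
    contaminant kingdoms each carry a small species chain so the
    contaminant filter is exercised.  Deterministic for a given config.
    """
    nodes = [TaxonomyNode(1, 1, NO_RANK, "root")]
    next_id = [2]

    def add(parent: int, rank: str, name: str) -> int:
        taxid = next_id[0]
        next_id[0] += 1
        nodes.append(TaxonomyNode(taxid, parent, rank, name))
        return taxid

    bacteria = add(1, "superkingdom", "Bacteria")
    eukaryota = add(1, "superkingdom", "Eukaryota")
    bacteria_k = add(bacteria, "kingdom", "Bacteria_incertae_sedis")
    fungi = add(eukaryota, "kingdom", "Fungi")
    viridiplantae = add(eukaryota, "kingdom", "Viridiplantae")
    metazoa = add(eukaryota, "kingdom", "Metazoa")

    def grow_clade(kingdom_taxid: int, prefix: str, n_species: int) -> list[int]:
        if n_species == 0:
            return []
        levels = list(cfg.ranks)
        # node counts per level, geometric interpolation to n_species
        counts = [
            max(1, int(np.ceil(n_species ** ((i + 1) / len(levels)))))
            for i in range(len(levels) - 1)
        ] + [n_species]
        level_ids: list[list[int]] = []
        for li, (rank, count) in enumerate(zip(levels, counts)):
            ids = []
            for i in range(count):
                if li == 0:
                    parent = kingdom_taxid
                else:
                    parent = level_ids[li - 1][i * len(level_ids[li - 1]) // count]
                ids.append(add(parent, rank, f"{prefix}_{rank}_{i}"))
            level_ids.append(ids)
        return level_ids[-1]

    n_bact = cfg.n_leaves // 2
    n_fungi = cfg.n_leaves - n_bact
    grow_clade(bacteria_k, "Bact", n_bact)
    grow_clade(fungi, "Fungi", n_fungi)

    # small contaminant chains
    for kingdom_taxid, prefix, n_sp in (
        (viridiplantae, "Plant", 2),
        (metazoa, "Animal", 1),
    ):
        phylum = add(kingdom_taxid, "phylum", f"{prefix}_phylum")
        fam = add(phylum, "family", f"{prefix}_family")
        genus = add(fam, "genus", f"{prefix}_genus")
        for i in range(n_sp):
            add(genus, "species", f"{prefix}_species_{i}")

    tree = TaxonomyTree(nodes)
    tree.contaminant_roots = (viridiplantae, metazoa)  # type: ignore[attr-defined]
    return tree


def species_taxids(tree: TaxonomyTree, contaminants: bool = False) -> list[int]:
    """Species-level taxids, optionally restricted to microbial clades."""
    excluded: set[int] = set()
    if not contaminants:
        roots = getattr(tree, "contaminant_roots", ())
        for taxid in tree.nodes:
            if tree.nodes[taxid].rank == "species" and any(
                r in tree.lineage(taxid) for r in roots
            ):
                excluded.add(taxid)
    return sorted(
        t
        for t, node in tree.nodes.items()
        if node.rank == "species" and t not in excluded
    )


# -- alignment hits ------------------------------------------------------


def simulate_hits(
    cfg: SyntheticConfig,
    tree: TaxonomyTree,
    composition: Optional[Mapping[int, float]] = None,
) -> tuple[list[AlignmentHit], pd.DataFrame]:
    """Per-read alignment hits with known source taxa.

    Each of ``cfg.n_reads`` reads is drawn from ``composition`` (uniform
    over microbial species if omitted; host reads mixed in at
    ``cfg.host_fraction`` from the plant clade).  With probability
    ``cfg.ambiguity_rate`` the read also hits a sibling species at equal
    score, which forces LCA promotion to the shared genus.  Percent
    identity is drawn as ``N(98, identity_noise_sd)`` clipped to
    [80, 100].

    Returns the hit list (grouped by read) and a truth table with the
    true source taxid and the expected assignment taxid per read.
    """
    rng = _rng(cfg, "simulate_hits")
    if composition is None:
        leaves = species_taxids(tree)
        composition = {t: 1.0 / len(leaves) for t in leaves}
    if not composition:
        raise ValueError("empty composition")
    taxa = sorted(composition)
    probs = np.array([composition[t] for t in taxa], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("composition must sum to 1")

    host_species = [
        t
        for t in species_taxids(tree, contaminants=True)
        if t not in set(species_taxids(tree))
    ]

    hits: list[AlignmentHit] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        read_id = f"r{i:06d}"
        if host_species and rng.random() < cfg.host_fraction:
            source = int(rng.choice(host_species))
        else:
            source = int(taxa[rng.choice(len(taxa), p=probs)])
        identity = float(np.clip(rng.normal(98.0, cfg.identity_noise_sd), 80.0, 100.0))
        score = float(rng.uniform(45.0, 55.0))
        start = int(rng.integers(0, 500))
        hits.append(
            AlignmentHit(
                read_id=read_id,
                subject_id=f"acc{source}",
                subject_taxid=source,
                percent_identity=identity,
                score=score,
                subject_start=start,
                subject_end=start + 50,
            )
        )
        expected = source if identity >= 97.0 else None
        siblings = [
            s
            for s in tree.nodes
            if tree.nodes[s].rank == "species"
            and tree.nodes[s].parent_taxid == tree.nodes[source].parent_taxid
            and s != source
        ]
        ambiguous = bool(siblings) and rng.random() < cfg.ambiguity_rate
        if ambiguous:
            sibling = int(rng.choice(siblings))
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    subject_id=f"acc{sibling}",
                    subject_taxid=sibling,
                    percent_identity=identity,
                    score=score,
                    subject_start=start,
                    subject_end=start + 50,
                )
            )
            if expected is not None:
                expected = tree.nodes[source].parent_taxid
        truth_rows.append(
            {
                "read_id": read_id,
                "true_taxid": source,
                "ambiguous": ambiguous,
                "expected_taxid": expected,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("read_id")
    return hits, truth


# -- count tables --------------------------------------------------------


def design_metadata(n_replicates: int = 3) -> pd.DataFrame:
    """The 2 genotypes x 3 soils x replicates sample sheet."""
    rows = {}
    for genotype in GENOTYPES:
        for soil in SOILS:
            for rep in range(1, n_replicates + 1):
                rows[f"{genotype}{soil}_R{rep}"] = {
                    "genotype": genotype,
                    "soil": soil,
                    "replicate": rep,
                }
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.index.name = "sample"
    return meta


def simulate_counts(
    cfg: SyntheticConfig,
    n_replicates: Optional[int] = None,
) -> tuple["CountTable", list[str]]:
    """Negative-binomial feature x sample counts over the full design.

    Feature baselines are log-normal; a ``cfg.affected_fraction`` subset
    of features carries a multiplicative ``cfg.effect_size`` enrichment
    in genotype "C" (effect 1 leaves the groups exchangeable).  Sample
    depths vary log-normally, which is what size-factor normalization
    has to undo.  Returns the table and the list of affected features.
    """
    from .tables import CountTable

    rng = _rng(cfg, "simulate_counts")
    n_replicates = n_replicates or cfg.n_samples_per_group
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    meta = design_metadata(n_replicates)
    n_features = cfg.n_features
    baselines = np.exp(rng.normal(np.log(100.0), 1.0, size=n_features))
    n_affected = int(round(cfg.affected_fraction * n_features))
    affected_idx = rng.choice(n_features, size=n_affected, replace=False)
    affected_mask = np.zeros(n_features, dtype=bool)
    affected_mask[affected_idx] = True

    depth = np.exp(rng.normal(0.0, 0.3, size=len(meta)))
    r = 1.0 / cfg.nb_dispersion  # NB size parameter
    counts = np.zeros((n_features, len(meta)), dtype=int)
    for j, sample in enumerate(meta.index):
        mu = baselines.copy()
        if meta.loc[sample, "genotype"] == "C":
            mu = np.where(affected_mask, mu * cfg.effect_size, mu)
        mu = mu * depth[j]
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)

    features = [f"F{i:03d}" for i in range(n_features)]
    table = CountTable(
        pd.DataFrame(counts, index=features, columns=meta.index), meta
    )
    return table, [features[i] for i in sorted(affected_idx)]


# -- references and mapped reads -----------------------------------------


def simulate_references_and_reads(
    cfg: SyntheticConfig,
    n_refs: int = 5,
    ref_length: int = 1000,
    read_length: int = 50,
    n_intervals: int = 100,
) -> tuple[ReferenceSet, list[MappedInterval]]:
    """Random references plus uniformly placed read intervals.

    Deliberately includes one interval flush against each reference
    end so boundary clipping is always exercised.
    """
    if ref_length < read_length:
        raise ValueError("reference shorter than the read length")
    rng = _rng(cfg, "simulate_references_and_reads")
    alphabet = np.array(list("ACGT"))
    refs = {
        f"ref{i}": "".join(rng.choice(alphabet, size=ref_length))
        for i in range(n_refs)
    }
    intervals = []
    ref_ids = sorted(refs)
    for i in range(n_intervals):
        ref_id = ref_ids[int(rng.integers(n_refs))]
        if i == 0:
            start = 0
        elif i == 1:
            start = ref_length - read_length
        else:
            start = int(rng.integers(0, ref_length - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        intervals.append(
            MappedInterval(
                ref_id=ref_id,
                start=start,
                end=start + read_length,
                strand=strand,
                read_id=f"pr{i:05d}",
            )
        )
    return ReferenceSet(refs), intervals
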