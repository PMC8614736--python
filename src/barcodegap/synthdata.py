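"""Synthetic catalogs, communities and sequence datasets.

The generators emulate the statistical structure the analysis assumes: a
checklist of ~82 species across six phyla dominated by Mollusca, Annelida
and Arthropoda (~93% of species), per-phylum barcode coverage in the
0.58-0.73 range, a 15-site x 2-season survey spanning a disturbance gradient
so that every quality class occurs, and, for the sequence stage, a species
tree with tight within-species accession clusters evolving under the K80
substitution model.  Every output is a pure function of its configuration
including the seed; a single global seed fans out to fixed per-stage child
streams so stages can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables_io import AlignedSequences, CommunityTable, SpeciesCatalog

#: Anchor disturbance tolerances of the five ecological groups (I sensitive
#: .. V first-order opportunist).
GROUP_TOLERANCE = {"I": 0.0, "II": 0.25, "III": 0.5, "IV": 0.75, "V": 1.0}

_STAGE = {"catalog": 1, "community": 2, "sequences": 3}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], int(seed)])


@dataclass
class SynthConfig:
    """Configuration of the catalog + community generator.

    Defaults are the "apulia-like" preset: 82 species, six phyla with the
    three dominant ones holding ~93% of species, per-phylum barcode
    probabilities 0.58 / 0.65 / 0.73 for Mollusca / Annelida / Arthropoda,
    15 sites sampled in two seasons over an even disturbance gradient.
    """

    seed: int = 0
    n_species: int = 82
    phylum_proportions: dict[str, float] = field(default_factory=lambda: {
        "Mollusca": 0.40, "Annelida": 0.28, "Arthropoda": 0.25,
        "Cnidaria": 0.03, "Echinodermata": 0.02, "Sipuncula": 0.02,
    })
    barcode_prob_per_phylum: dict[str, float] = field(default_factory=lambda: {
        "Mollusca": 0.58, "Annelida": 0.65, "Arthropoda": 0.73,
        "Cnidaria": 0.64, "Echinodermata": 0.64, "Sipuncula": 0.64,
    })
    eg_proportions: dict[str, float] = field(default_factory=lambda: {
        "I": 0.25, "II": 0.20, "III": 0.20, "IV": 0.15, "V": 0.10,
        "NA": 0.10,
    })
    n_sites: int = 15
    seasons: tuple[str, ...] = ("fall", "spring")
    disturbance_per_site: dict[str, float] | None = None
    occupancy_max: float = 0.7
    tolerance_width: float = 0.25
    abundance_mean_log: float = 2.0
    abundance_sd_log: float = 1.0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        total = sum(self.phylum_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"phylum proportions must sum to 1 (got {total})")
        for name, probs in (("barcode", self.barcode_prob_per_phylum),
                            ("ecological-group", self.eg_proportions)):
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"{name} probability for {key} outside [0, 1]: {p}")
        if abs(sum(self.eg_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("ecological-group proportions must sum to 1")
        missing = set(self.phylum_proportions) - set(
            self.barcode_prob_per_phylum)
        if missing:
            raise ConfigError(
                f"no barcode probability for phyla: {sorted(missing)}")

    def site_disturbances(self) -> dict[str, float]:
        if self.disturbance_per_site is not None:
            return dict(self.disturbance_per_site)
        if self.n_sites == 1:
            return {"site01": 0.5}
        return {f"site{i + 1:02d}": i / (self.n_sites - 1)
                for i in range(self.n_sites)}


def apulia_like_config(seed: int = 0, **overrides) -> SynthConfig:
    """The default preset emulating a 15-site, two-season lagoon survey."""
    return SynthConfig(seed=seed, **overrides)


def simulate_catalog(config: SynthConfig) -> SpeciesCatalog:
    """Draw a species catalog: phyla by the proportion vector, ecological
    groups by the configured mixture, barcode availability by per-phylum
    Bernoulli draws.

    The per-phylum probability governs the *union* coverage (barcoded in at
    least one library); barcoded species are then attributed to BOLD and/or
    GenBank with at least one flag set.
    """
    rng = _rng(config.seed, "catalog")
    phyla = list(config.phylum_proportions)
    probs = np.array([config.phylum_proportions[p] for p in phyla])
    phylum_draw = rng.choice(len(phyla), size=config.n_species, p=probs)
    groups = list(config.eg_proportions)
    gprobs = np.array([config.eg_proportions[g] for g in groups])
    group_draw = rng.choice(len(groups), size=config.n_species, p=gprobs)

    rows = []
    for i in range(config.n_species):
        ph = phyla[phylum_draw[i]]
        barcoded = rng.random() < config.barcode_prob_per_phylum[ph]
        if barcoded:
            in_bold = rng.random() < 0.8
            in_genbank = rng.random() < 0.7
            if not (in_bold or in_genbank):
                in_bold = True
        else:
            in_bold = in_genbank = False
        rows.append({
            "taxon_name": f"Synthspecies {i + 1:05d}",
            "phylum": ph,
            "ecological_group": groups[group_draw[i]],
            "barcoded_bold": in_bold,
            "barcoded_genbank": in_genbank,
            "primer_reported": None,
        })
    return SpeciesCatalog(pd.DataFrame(rows))


def simulate_communities(config: SynthConfig,
                         catalog: SpeciesCatalog) -> CommunityTable:
    """Draw a long-format community table over the configured site grid.

    Species occupancy decreases with the distance between a site's
    disturbance level and the species' tolerance (anchored to its ecological
    group; not-assigned species get a latent uniform tolerance), so
    low-disturbance sites are enriched in groups I-II and high-disturbance
    sites in IV-V, and expected AMBI rises monotonically with disturbance.
    Abundances are log-normal, rounded up to at least one individual.
    """
    rng = _rng(config.seed, "community")
    groups = catalog.df["ecological_group"].tolist()
    taxa = catalog.taxa
    tolerance = np.array([
        GROUP_TOLERANCE.get(g, np.nan) for g in groups
    ])
    latent = rng.uniform(0.0, 1.0, size=len(taxa))
    tolerance = np.where(np.isnan(tolerance), latent, tolerance)

    rows = []
    for site, disturbance in sorted(config.site_disturbances().items()):
        for season in config.seasons:
            z = (disturbance - tolerance) / config.tolerance_width
            p_occ = config.occupancy_max * np.exp(-0.5 * z * z)
            present = rng.random(len(taxa)) < p_occ
            counts = np.maximum(1.0, np.round(rng.lognormal(
                config.abundance_mean_log, config.abundance_sd_log,
                size=len(taxa))))
            for i in np.flatnonzero(present):
                rows.append({"site_id": site, "season": season,
                             "taxon_name": taxa[i],
                             "abundance": float(counts[i])})
    df = pd.DataFrame(rows, columns=["site_id", "season", "taxon_name",
                                     "abundance"])
    keys = tuple(sorted(
        (site, season)
        for site in config.site_disturbances()
        for season in config.seasons))
    return CommunityTable(df, sample_keys=keys, seasons=config.seasons)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

@dataclass
class SeqSimConfig:
    """Configuration of the COI-like sequence simulator.

    ``between_species_scale`` is the mean length (substitutions per site) of
    the species-tree edges (i.i.d. exponential, matching the speciation
    process of the delimitation model); ``within_species_scale`` is the
    coalescent scale of the accession subtrees.  Their ratio controls how
    cleanly species separate (default ratio 20, with absolute values in the
    range of typical COI barcode divergences).
    """

    seed: int = 0
    n_species: int = 10
    accessions_per_species: tuple[int, int] = (3, 3)
    between_species_scale: float = 0.05
    within_species_scale: float = 0.0025
    kappa: float = 4.0
    seq_length: int = 600

    def __post_init__(self) -> None:
        if self.between_species_scale <= 0 or self.within_species_scale <= 0:
            raise ConfigError("branch-length scales must be positive")
        if self.seq_length < 50:
            raise ConfigError("seq_length must be >= 50")
        lo, hi = self.accessions_per_species
        if not (1 <= lo <= hi):
            raise ConfigError("invalid accessions_per_species range")
        if self.n_species < 2:
            raise ConfigError("need at least 2 species")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")


def _coalescent_topology(labels: list[str], scale: float,
                         rng: np.random.Generator) -> dendropy.Node:
    """Random coalescent over the given tips: nodes carry ``depth`` (time
    below the present); returns the root node.  Branch lengths are assigned
    by the caller from depth differences."""
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.depth = 0.0
        nd.sim_label = lab
        nodes.append(nd)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(scale / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.depth = t
        parent.sim_label = None
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = parent.depth - a.depth
        b.edge.length = parent.depth - b.depth
        nodes = [nd for p, nd in enumerate(nodes) if p not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _species_tree(labels: list[str], scale: float,
                  rng: np.random.Generator) -> dendropy.Node:
    """Random species-tree topology with shifted-exponential branch lengths.

    Edges are 0.3*scale + Exp(mean 0.7*scale), i.e. exponential speciation
    waiting times with a minimum interspecific divergence of 30% of the
    scale.  The floor encodes the barcoding gap seen in real COI datasets
    (congeneric species essentially never sit at ~0 divergence), so the
    generated data has the separation structure the delimitation analysis
    assumes."""
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.sim_label = lab
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.sim_label = None
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(0.3 * scale + rng.exponential(0.7 * scale))
        b.edge.length = float(0.3 * scale + rng.exponential(0.7 * scale))
        nodes = [nd for p, nd in enumerate(nodes) if p not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """K80 transition probabilities for branch length t (expected
    substitutions per site): returns (p_transition, p_each_transversion)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # per transversion target (two targets)
    return p_ts, p_tv


_BASES = np.array(list("ACGT"))
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T on indices 0..3
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _evolve(parent_states: np.ndarray, t: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    p_ts, p_tv = _k80_probs(max(t, 0.0), kappa)
    u = rng.random(parent_states.shape)
    child = parent_states.copy()
    is_ts = (u >= 1.0 - p_ts - 2.0 * p_tv) & (u < 1.0 - 2.0 * p_tv)
    is_tv = u >= 1.0 - 2.0 * p_tv
    child[is_ts] = _TRANSITION[parent_states[is_ts]]
    pick = (rng.random(int(is_tv.sum())) < 0.5).astype(int)
    child[is_tv] = _TRANSVERSIONS[parent_states[is_tv], pick]
    return child


def simulate_sequences(config: SeqSimConfig) -> tuple[
        AlignedSequences, dict[str, str], dendropy.Tree]:
    """Simulate an aligned accession set with known species structure.

    Builds a random species tree with exponential edge lengths at the
    between-species scale, grafts a
    within-species coalescent of accessions onto each species tip, evolves
    sequences along the tree under K80(kappa), and returns the alignment,
    the true accession -> species map, and the generating tree (leaves
    labelled by accession).
    """
    rng = _rng(config.seed, "sequences")
    species = [f"Synthsp {i + 1:03d}" for i in range(config.n_species)]
    root = _species_tree(species, config.between_species_scale, rng)

    truth: dict[str, str] = {}
    lo, hi = config.accessions_per_species
    taxon_namespace = dendropy.TaxonNamespace()
    for leaf in [nd for nd in root.leaf_iter()]:
        sp = leaf.sim_label
        n_acc = int(rng.integers(lo, hi + 1))
        acc_labels = [f"{sp.replace(' ', '_')}_acc{k + 1}"
                      for k in range(n_acc)]
        for lab in acc_labels:
            truth[lab] = sp
        if n_acc == 1:
            leaf.taxon = taxon_namespace.new_taxon(acc_labels[0])
            continue
        sub_root = _coalescent_topology(acc_labels,
                                        config.within_species_scale, rng)
        # graft: the species tip becomes the accession subtree root
        for child in sub_root.child_nodes():
            leaf.add_child(child)
        leaf.sim_label = None
        for nd in leaf.leaf_iter():
            nd.taxon = taxon_namespace.new_taxon(nd.sim_label)

    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    tree.is_rooted = True

    # evolve sequences root-to-tips
    states: dict[int, np.ndarray] = {
        id(root): rng.integers(0, 4, size=config.seq_length)
    }
    sequences: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd is root:
            parent_states = states[id(root)]
        else:
            parent_states = _evolve(states[id(nd.parent_node)],
                                    float(nd.edge.length or 0.0),
                                    config.kappa, rng)
            states[id(nd)] = parent_states
        if nd.is_leaf():
            sequences[nd.taxon.label] = "".join(_BASES[parent_states])

    accessions = sorted(sequences)
    aln = AlignedSequences(
        accessions=accessions,
        species=[truth[a] for a in accessions],
        sequences=[sequences[a] for a in accessions],
    )
    return aln, truth, tree
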