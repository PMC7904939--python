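"""Synthetic benchmark generator with a planted similarity-driven signal.

Emulates the shape of a kinase-panel affinity study at desk scale: a drug
roster of valid SMILES organised into scaffold clusters, a target roster of
amino-acid sequences organised into consensus-sequence families, and a
partially missing affinity matrix whose values depend on the (drug cluster,
target cluster) combination.  Because affinity is a function of cluster
identity, and cluster identity is recoverable from the Tanimoto /
normalized-SW similarity structure, a similarity-based model can recover
the signal — which is exactly what the end-to-end tests exercise.

Chemical validity is guaranteed by construction (scaffold + alkyl chain +
terminal substituent), so the generator itself needs no chemistry
dependency.  It does not attempt realistic kinase chemistry or the bimodal
affinity distribution of real panels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import Drug, Target
from .data import AffinityDataset, write_dataset

__all__ = [
    "SyntheticSpec",
    "generate_drugs",
    "generate_targets",
    "generate_affinities",
    "generate_dataset",
    "write_synthetic_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one ring scaffold per cluster; appending chains/substituents keeps SMILES valid
SCAFFOLDS = [
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "C1CCCCC1",        # cyclohexane
    "c1ccsc1",         # thiophene
    "C1CCNCC1",        # piperidine
    "c1ccoc1",         # furan
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCOC1",         # tetrahydrofuran
]
TERMINALS = ["O", "N", "Cl", "F", "C(=O)O", "OC", "Br", ""]

BASE_AFFINITY = 5.0  # pKd-like baseline, the weak-binding floor of Kd panels


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 20
    n_targets: int = 15
    n_drug_clusters: int = 4
    n_target_clusters: int = 3
    signal_strength: float = 2.0
    noise_sd: float = 0.3
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 1 or self.n_targets < 1:
            raise ValueError("need at least one drug and one target")
        if not (1 <= self.n_drug_clusters <= self.n_drugs):
            raise ValueError("drug cluster count must be in [1, n_drugs]")
        if not (1 <= self.n_target_clusters <= self.n_targets):
            raise ValueError("target cluster count must be in [1, n_targets]")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValueError("signal_strength and noise_sd must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _drug_cluster(i: int, spec: SyntheticSpec) -> int:
    return i % spec.n_drug_clusters


def _target_cluster(j: int, spec: SyntheticSpec) -> int:
    return j % spec.n_target_clusters


def generate_drugs(spec: SyntheticSpec) -> list[Drug]:
    """Cluster-structured valid SMILES: cluster scaffold + homologous chain
    + cycled terminal group, so within-cluster Tanimoto exceeds
    between-cluster on average."""
    drugs = []
    member_count = [0] * spec.n_drug_clusters
    for i in range(spec.n_drugs):
        c = _drug_cluster(i, spec)
        m = member_count[c]
        member_count[c] += 1
        scaffold = SCAFFOLDS[c % len(SCAFFOLDS)]
        chain = "C" * (1 + m % 4)
        terminal = TERMINALS[m % len(TERMINALS)]
        drugs.append(Drug(f"D{i:03d}", scaffold + chain + terminal))
    return drugs


def generate_targets(spec: SyntheticSpec) -> list[Target]:
    """Cluster-structured sequences: a random consensus per cluster
    (length 100-300) with 10% per-position mutations per member."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    consensus = []
    for _ in range(spec.n_target_clusters):
        length = int(rng.integers(100, 301))
        consensus.append(rng.choice(aa, size=length))
    targets = []
    for j in range(spec.n_targets):
        c = _target_cluster(j, spec)
        seq = consensus[c].copy()
        mutate = rng.random(seq.size) < 0.10
        seq[mutate] = rng.choice(aa, size=int(mutate.sum()))
        targets.append(Target(f"T{j:03d}", "".join(seq)))
    return targets


def generate_affinities(
    drugs: list[Drug], targets: list[Target], spec: SyntheticSpec
) -> AffinityDataset:
    """Planted-signal affinity matrix on a pKd-like scale.

    y_ij = base + signal_strength * effect[cluster(drug i), cluster(target j)]
           + N(0, noise_sd), with the cluster-effect matrix drawn once per
    seed from a standard normal; cells go missing independently at
    ``missing_rate`` (at least one observation is always kept).
    """
    rng = np.random.default_rng(spec.seed + 1)
    effect = rng.standard_normal((spec.n_drug_clusters, spec.n_target_clusters))
    nd, nt = len(drugs), len(targets)
    y = np.empty((nd, nt))
    for i in range(nd):
        for j in range(nt):
            y[i, j] = (
                BASE_AFFINITY
                + spec.signal_strength
                * effect[_drug_cluster(i, spec), _target_cluster(j, spec)]
            )
    y += rng.normal(0.0, spec.noise_sd, size=y.shape)
    observed = rng.random(y.shape) >= spec.missing_rate
    if not observed.any():
        observed[0, 0] = True
    y = np.where(observed, y, np.nan)
    return AffinityDataset(tuple(drugs), tuple(targets), y, observed, scale="pKd")


def generate_dataset(spec: SyntheticSpec | None = None) -> AffinityDataset:
    spec = spec or SyntheticSpec()
    drugs = generate_drugs(spec)
    targets = generate_targets(spec)
    return generate_affinities(drugs, targets, spec)


def write_synthetic_dataset(spec: SyntheticSpec, out_dir) -> dict:
    """Write the three canonical input files plus a manifest recording the
    generating conditions and seed."""
    ds = generate_dataset(spec)
    paths = write_dataset(ds, out_dir)
    manifest = Path(out_dir) / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"generator": "simdta.synthetic", "spec": asdict(spec),
                   "scale": ds.scale}, fh, indent=1)
    paths["manifest"] = manifest
    return paths
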