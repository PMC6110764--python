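"""Seeded synthetic PSSM datasets with tunable class separation.

Real golden-standard interaction datasets pair evolutionary profiles from
a curated interaction database with negatives drawn across subcellular
compartments. This generator emulates that structure with a latent-cluster
model: proteins belong to latent clusters (the compartment analogy), each
protein has a latent 20-vector near its cluster center, and PSSM rows are
integer-rounded noisy draws around that vector, clipped to the usual
log-odds range [-10, 12]. Interacting pairs are sampled within a cluster,
non-interacting pairs across clusters, so the separation parameter (the
spread of the cluster centers) controls how detectable interaction is:
at separation 0 the centers coincide and the labels carry no signal.

Everything is driven by one seed; the same config reproduces byte-identical
PSSM files and pair lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pssm_io import PSSM, PairDataset, read_pair_list, write_pair_list, write_pssm

__all__ = [
    "SyntheticConfig",
    "ProteinSet",
    "generate_proteins",
    "generate_pairs",
    "write_dataset",
    "generate_dataset",
]

#: PSI-BLAST log-odds scores in practice fall in this integer range.
SCORE_MIN, SCORE_MAX = -10, 12


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    n_proteins : proteins to simulate (split evenly over clusters).
    n_pairs_per_class : pairs per label; classes are exactly balanced.
    length_range : inclusive (min, max) residue count per protein.
    separation : spread (per-coordinate s.d.) of the latent cluster
        centers; 0 removes all class signal.
    noise_sd : per-residue score noise around the latent profile.
    n_clusters : latent clusters (compartment analogy); >= 2.
    within_sd : per-protein jitter around its cluster center.
    center_seed : separate seed for the cluster centers; defaults to
        ``seed``. Two configs sharing a center_seed but differing in seed
        describe disjoint protein universes under the same generative
        parameters (the cross-species setting).
    """

    n_proteins: int = 200
    n_pairs_per_class: int = 250
    length_range: tuple[int, int] = (50, 200)
    separation: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    n_clusters: int = 2
    within_sd: float = 0.5
    center_seed: int | None = None
    id_prefix: str = "P"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_pairs_per_class < 1:
            raise ValueError("n_pairs_per_class must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_clusters < 2:
            raise ValueError("need >= 2 latent clusters")
        if self.n_proteins < 2 * self.n_clusters:
            raise ValueError("need at least 2 proteins per cluster")


@dataclass
class ProteinSet:
    """Generated proteins: PSSMs plus their latent cluster assignment."""

    pssms: dict[str, PSSM]
    clusters: dict[str, int]

    def __len__(self) -> int:
        return len(self.pssms)


def generate_proteins(config: SyntheticConfig) -> ProteinSet:
    """Simulate one PSSM per protein from the latent-cluster model.

    Protein i joins cluster i mod n_clusters; its latent profile is the
    cluster center plus within-cluster jitter, and each residue row is the
    profile plus Gaussian noise, rounded to integers and clipped to the
    log-odds range. Deterministic per (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    center_seed = config.seed if config.center_seed is None else config.center_seed
    centers = config.separation * np.random.default_rng(
        center_seed
    ).standard_normal((config.n_clusters, 20))
    lo, hi = config.length_range
    width = len(str(config.n_proteins))

    pssms: dict[str, PSSM] = {}
    clusters: dict[str, int] = {}
    for i in range(config.n_proteins):
        pid = f"{config.id_prefix}{i + 1:0{width}d}"
        c = i % config.n_clusters
        u = centers[c] + config.within_sd * rng.standard_normal(20)
        n = int(rng.integers(lo, hi + 1))
        rows = u + config.noise_sd * rng.standard_normal((n, 20))
        scores = np.clip(np.rint(rows), SCORE_MIN, SCORE_MAX).astype(np.int64)
        pssms[pid] = PSSM(protein_id=pid, scores=scores)
        clusters[pid] = c
    return ProteinSet(pssms=pssms, clusters=clusters)


def generate_pairs(proteins: ProteinSet, config: SyntheticConfig) -> PairDataset:
    """Sample balanced labelled pairs: positives within a cluster,
    negatives across clusters, no duplicates (unordered)."""
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    rng = np.random.default_rng(config.seed + 1)
    by_cluster: dict[int, list[str]] = {}
    for pid, c in proteins.clusters.items():
        by_cluster.setdefault(c, []).append(pid)
    sizes = {c: len(ids) for c, ids in by_cluster.items()}
    n_within = sum(m * (m - 1) // 2 for m in sizes.values())
    total = sum(sizes.values())
    n_cross = (total * total - sum(m * m for m in sizes.values())) // 2
    if config.n_pairs_per_class > n_within or config.n_pairs_per_class > n_cross:
        raise ValueError(
            f"requested {config.n_pairs_per_class} pairs/class but only "
            f"{n_within} within-cluster and {n_cross} cross-cluster "
            "combinations exist"
        )

    cluster_ids = sorted(by_cluster)
    used: set[frozenset[str]] = set()
    pairs: list[tuple[str, str, int]] = []

    def draw(label: int) -> None:
        while True:
            if label == 1:
                eligible = [c for c in cluster_ids if sizes[c] >= 2]
                c = eligible[rng.integers(len(eligible))]
                a, b = rng.choice(by_cluster[c], size=2, replace=False)
            else:
                ca, cb = rng.choice(cluster_ids, size=2, replace=False)
                a = by_cluster[ca][rng.integers(sizes[ca])]
                b = by_cluster[cb][rng.integers(sizes[cb])]
            key = frozenset((a, b))
            if key not in used:
                used.add(key)
                pairs.append((str(a), str(b), label))
                return

    for _ in range(config.n_pairs_per_class):
        draw(1)
    for _ in range(config.n_pairs_per_class):
        draw(0)
    return PairDataset(pairs, proteins.pssms)


def write_dataset(
    proteins: ProteinSet, dataset: PairDataset, out_dir: str | Path
) -> Path:
    """Write '<id>.pssm' files and 'pairs.tsv' into a directory; returns
    the pair-list path. The directory is consumable by read_pair_list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pid, pssm in proteins.pssms.items():
        write_pssm(pssm, out_dir / f"{pid}.pssm")
    pair_path = out_dir / "pairs.tsv"
    write_pair_list(dataset.pairs, pair_path)
    return pair_path


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> PairDataset:
    """Generate proteins and pairs; if ``out_dir`` is given, write the
    dataset to disk and load it back through the parsers (so file I/O is
    part of the exercised path)."""
    proteins = generate_proteins(config)
    dataset = generate_pairs(proteins, config)
    if out_dir is not None:
        pair_path = write_dataset(proteins, dataset, out_dir)
        return read_pair_list(pair_path, Path(out_dir))
    return dataset
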