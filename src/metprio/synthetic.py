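"""Seeded synthetic fixtures for end-to-end testing without downloads.

The generator emulates the premise that similar diseases relate to similar
metabolites: metabolite descriptor vectors are isotropic Gaussian blobs
around cluster centroids, one cluster is designated focal-associated
(positives, with optional label flips), the middle clusters are assigned to
non-focal diseases (the SP negative pool), and the last cluster is left
unassigned (the SM pool).  The disease table is a focal-centered star with
similarities drawn uniformly from a configured range.

Centroid coordinates are drawn N(0, cluster_separation^2) against unit
per-coordinate noise, so the expected within-cluster cosine similarity is
roughly sep^2 / (sep^2 + 1) regardless of descriptor width, and
cluster_separation = 0 degenerates to pure noise.

All outputs are deterministic functions of the FixtureSpec (seed included) and are
written in exactly the external formats the other modules read, so fixtures
double as format round-trip tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError
from .assoc import AssociationSet
from .networks import DescriptorMatrix

PADEL_DESCRIPTOR_WIDTH = 2325  # width of a full PaDEL-Descriptor vector


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study.

    Defaults give 200 metabolites in 4 well-separated clusters (50 focal
    positives, 100 SP-pool, 50 SM-pool) over 100 descriptors — a small but
    structurally faithful stand-in for a real descriptor table.
    """

    n_metabolites: int = 200
    n_descriptors: int = 100
    n_clusters: int = 4
    cluster_separation: float = 4.0
    assoc_noise: float = 0.0
    n_diseases: int = 4
    focal_similarity_range: tuple[float, float] = (0.3, 0.9)
    baseline_offset: float = 2.0
    seed: int = 0
    focal_disease: str = "D_FOCAL"

    def __post_init__(self):
        if self.n_clusters > self.n_metabolites:
            raise DataError("more clusters than metabolites")
        if self.n_clusters < 3:
            raise DataError(
                "need >= 3 clusters: one focal, >= 1 for the SP pool, "
                "one unassigned for the SM pool"
            )
        if not (0.0 <= self.assoc_noise < 0.5):
            raise DataError("assoc_noise must be in [0, 0.5)")
        if self.cluster_separation < 0:
            raise DataError("cluster_separation must be non-negative")
        if self.n_diseases < 2:
            raise DataError("need the focal disease plus >= 1 other")
        lo, hi = self.focal_similarity_range
        if not (0 <= lo <= hi):
            raise DataError("invalid focal_similarity_range")


@dataclass
class SyntheticFixture:
    descriptors: DescriptorMatrix
    disease_table: list[tuple[str, str, float]]
    associations: AssociationSet
    ground_truth: dict


def generate_fixture(spec: FixtureSpec) -> SyntheticFixture:
    """Draw a complete synthetic study from ``spec`` (byte-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_metabolites, spec.n_descriptors, spec.n_clusters

    met_ids = [f"M{i:04d}" for i in range(n)]
    cluster_of = np.arange(n) % k  # balanced assignment
    centroids = rng.normal(0.0, spec.cluster_separation, size=(k, d))
    # positive baseline emulates the predominantly nonnegative scale of real
    # chemical descriptors, keeping pairwise cosines (and hence weighted
    # degrees) positive even with no cluster structure
    values = spec.baseline_offset + centroids[cluster_of] + rng.normal(0.0, 1.0, size=(n, d))
    # a zero-norm row is a measure-zero event; regenerate defensively
    norms = np.linalg.norm(values, axis=1)
    while np.any(norms == 0):  # pragma: no cover
        values[norms == 0] = rng.normal(0.0, 1.0, size=(int((norms == 0).sum()), d))
        norms = np.linalg.norm(values, axis=1)
    descriptors = DescriptorMatrix(met_ids, values)

    other_diseases = [f"D{i:03d}" for i in range(1, spec.n_diseases)]
    sims = rng.uniform(*spec.focal_similarity_range, size=len(other_diseases))
    disease_table = [
        (spec.focal_disease, dz, round(float(s), 6))
        for dz, s in zip(other_diseases, sims)
    ]

    # cluster 0 -> focal; clusters 1..k-2 -> non-focal diseases round-robin;
    # cluster k-1 -> unassigned (SM pool)
    in_focal_cluster = cluster_of == 0
    flips = rng.random(n) < spec.assoc_noise
    is_positive = in_focal_cluster ^ flips
    if not np.any(is_positive):
        raise DataError("fixture produced no positive associations")

    pairs: set[tuple[str, str]] = set()
    sm_pool: set[str] = set()
    for i, met in enumerate(met_ids):
        if is_positive[i]:
            pairs.add((spec.focal_disease, met))
        c = cluster_of[i]
        if 1 <= c <= k - 2:
            dz = other_diseases[(c - 1) % len(other_diseases)]
            pairs.add((dz, met))
        elif c == k - 1 and not is_positive[i]:
            sm_pool.add(met)

    associations = AssociationSet(pairs, spec.focal_disease, sm_pool)
    ground_truth = {
        "clusters": {met: int(c) for met, c in zip(met_ids, cluster_of)},
        "focal_cluster": 0,
        "positives": sorted(m for i, m in enumerate(met_ids) if is_positive[i]),
        "sp_pool": sorted(associations.sp_negative_pool()),
        "sm_pool": sorted(sm_pool),
        "spec": {**asdict(spec),
                 "focal_similarity_range": list(spec.focal_similarity_range)},
    }
    return SyntheticFixture(descriptors, disease_table, associations, ground_truth)


def write_fixture(fix: SyntheticFixture, outdir) -> dict[str, Path]:
    """Write the fixture in the pipeline's input formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "descriptors": outdir / "descriptors.tsv",
        "disease_similarity": outdir / "disease_similarity.tsv",
        "associations": outdir / "associations.tsv",
        "no_disease": outdir / "no_disease_metabolites.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    desc = fix.descriptors
    pd.DataFrame(
        desc.values,
        index=desc.metabolite_ids,
        columns=[f"desc{i}" for i in range(desc.n_descriptors)],
    ).rename_axis("metabolite_id").to_csv(
        paths["descriptors"], sep="\t", float_format="%.12g"
    )
    pd.DataFrame(fix.disease_table,
                 columns=["disease_a", "disease_b", "score"]).to_csv(
        paths["disease_similarity"], sep="\t", index=False, float_format="%.12g")
    pd.DataFrame(sorted(fix.associations.pairs),
                 columns=["disease_id", "metabolite_id"]).to_csv(
        paths["associations"], sep="\t", index=False)
    with open(paths["no_disease"], "w") as fh:
        for m in sorted(fix.associations.no_disease_metabolites or ()):
            fh.write(m + "\n")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(fix.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
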