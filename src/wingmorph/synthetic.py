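"""Synthetic landmark datasets with known ground truth.

Emulates the data-generating process behind multi-species wing-landmark
studies: species mean shapes at a controlled pairwise Procrustes divergence,
within-species isotropic shape variation, arbitrary digitizing frames
(random similarity transforms), and the two-component digitization error
model — a *persistent* per-landmark offset fixed for each user (the
systematic pointing bias that produces the user effect) plus fresh i.i.d.
pointing noise for every digitization.  Both error components act in image
space, before nothing — i.e. on the specimen's rendered coordinates — and
scale with the specimen's centroid size, since pointing error is
proportional to the structure's rendered size.

Every generator takes an explicit seed; outputs are byte-identical across
runs with the same seed.  Ground truth (species labels, planted separations
and variance components) travels with the datasets as a machine-readable
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .landmark_io import LandmarkConfiguration, LandmarkDataset
from .superimposition import _to_real, _unit_preshape_z, centroid_size

__all__ = [
    "SimulationScenario",
    "make_template",
    "simulate_species_means",
    "simulate_specimens",
    "apply_user_effect",
    "simulate_replicates",
    "simulate_user_study",
    "simulate_digitization_designs",
    "bayes_error_oracle",
    "generate_scenario",
]

# Stylized 11-point insect wing: vein intersections and margin points along a
# right wing in roughly anatomical arrangement; deliberately non-symmetric
# and non-collinear so all warp spaces are well defined.
_WING_11 = np.array(
    [
        [0.00, 0.10],  # wing base
        [0.55, 0.42],  # anterior margin, proximal
        [1.30, 0.55],  # anterior margin, mid
        [2.10, 0.48],  # anterior margin, distal
        [2.60, 0.25],  # wing tip
        [2.25, -0.05],  # posterior margin, distal
        [1.60, -0.22],  # posterior margin, mid
        [0.85, -0.28],  # posterior margin, proximal
        [1.05, 0.18],  # cross-vein intersection, anterior
        [1.55, 0.10],  # cross-vein intersection, central
        [1.95, 0.20],  # cross-vein intersection, distal
    ]
)


@dataclass
class SimulationScenario:
    """Complete recipe for a synthetic multi-species digitization study."""

    k: int = 11
    template: str = "wing"
    n_species: int = 2
    separation: float = 0.05
    sigma_shape: float = 0.01
    n_per_species: int = 44
    n_replicates: int = 1
    user_specs: list[dict] = field(default_factory=list)  # user_id/delta_persistent/sigma_point
    seed: int = 0

    def __post_init__(self):
        for name in ("separation", "sigma_shape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for spec in self.user_specs:
            if spec.get("delta_persistent", 0) < 0 or spec.get("sigma_point", 0) < 0:
                raise ValueError("user-effect magnitudes must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        payload = {
            "k": self.k,
            "template": self.template,
            "n_species": self.n_species,
            "separation": self.separation,
            "sigma_shape": self.sigma_shape,
            "n_per_species": self.n_per_species,
            "n_replicates": self.n_replicates,
            "user_specs": self.user_specs,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def make_template(k: int, kind: str = "wing") -> LandmarkConfiguration:
    """Base mean shape at unit centroid size.

    ``polygon`` is a regular k-gon (k >= 3); ``wing`` is the fixed 11-point
    stylized wing above (k >= 4), truncated to the first k points or extended
    by interpolating outline midpoints for other k.
    """
    if kind == "polygon":
        if k < 3:
            raise ValueError("polygon template needs k >= 3")
        ang = 2 * np.pi * np.arange(k) / k
        xy = np.column_stack([np.cos(ang), np.sin(ang)])
    elif kind == "wing":
        if k < 4:
            raise ValueError("wing template needs k >= 4")
        xy = _WING_11.copy()
        if k < 11:
            xy = xy[:k]
        elif k > 11:
            extra = []
            for i in range(k - 11):
                a, b = xy[i % 10], xy[i % 10 + 1]
                extra.append(0.5 * (a + b) + [0.013 * (i + 1), -0.007 * (i + 1)])
            xy = np.vstack([xy, extra])
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    z = _unit_preshape_z(xy)
    return LandmarkConfiguration(specimen_id=f"template-{kind}-{k}", coords=_to_real(z))


def _tangent_direction(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit direction in the tangent space at unit preshape z.

    Orthogonal (complex-Hermitian) to z — i.e. orthogonal to both the scale
    and rotation directions — and centered, so moving along it changes shape
    only.
    """
    k = z.shape[0]
    v = rng.normal(size=k) + 1j * rng.normal(size=k)
    v -= v.mean()
    v -= np.vdot(z, v) * z  # remove scale and rotation components at once
    return v / np.linalg.norm(v)


def simulate_species_means(
    template: LandmarkConfiguration, n_species: int, separation: float, seed: int
) -> list[LandmarkConfiguration]:
    """Species mean shapes at an exact partial Procrustes distance from the template.

    Each mean is the template moved along a random tangent direction on the
    preshape sphere by the geodesic angle rho = 2*arcsin(separation/2), which
    makes its partial Procrustes distance from the template equal
    ``separation`` exactly.  Pairwise distances among the means are recorded
    in each configuration's ``extra``.
    """
    rng = np.random.default_rng(seed)
    z0 = _unit_preshape_z(template.coords)
    rho = 2.0 * np.arcsin(min(separation / 2.0, 1.0))
    means = []
    for s in range(n_species):
        v = _tangent_direction(z0, rng)
        zm = np.cos(rho) * z0 + np.sin(rho) * v
        means.append(
            LandmarkConfiguration(
                specimen_id=f"species_{s + 1}",
                coords=_to_real(zm),
                species=f"species_{s + 1}",
                extra={"true_distance_from_template": separation},
            )
        )
    from .superimposition import procrustes_distance

    for i, mi in enumerate(means):
        for j, mj in enumerate(means):
            if i < j:
                d = procrustes_distance(mi, mj)
                mi.extra[f"true_distance_to_{mj.species}"] = d
                mj.extra[f"true_distance_to_{mi.species}"] = d
    return means


def _random_similarity(xy: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Arbitrary digitizing frame: rotation, log-uniform scale, bounded shift."""
    theta = rng.uniform(0, 2 * np.pi)
    scale = np.exp(rng.uniform(-0.2, 0.2))
    shift = rng.uniform(-1.0, 1.0, size=2)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return scale * xy @ R.T + shift


def simulate_specimens(
    means: list[LandmarkConfiguration],
    n_per_species: int,
    sigma_shape: float,
    seed: int,
) -> LandmarkDataset:
    """Species-labeled specimens around their mean shapes.

    Each specimen is its species mean plus i.i.d. Gaussian coordinate noise
    of SD ``sigma_shape`` (on the unit-CS mean), then pushed through a random
    similarity transform emulating an arbitrary digitizing frame.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for mean in means:
        for i in range(n_per_species):
            noisy = mean.coords + rng.normal(scale=sigma_shape, size=mean.coords.shape)
            xy = _random_similarity(noisy, rng)
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{mean.species}_{i + 1:03d}",
                    coords=xy,
                    species=mean.species,
                )
            )
    return LandmarkDataset(configs, provenance=f"simulated(seed={seed})")


def apply_user_effect(
    dataset: LandmarkDataset,
    user_id: str,
    delta_persistent: float,
    sigma_point: float,
    seed: int,
) -> LandmarkDataset:
    """Digitization of a dataset by one user.

    One fixed offset vector per landmark — drawn once for the user from an
    isotropic Gaussian with SD ``delta_persistent`` — is added to every
    specimen the user digitizes, plus fresh i.i.d. pointing noise of SD
    ``sigma_point`` per digitization.  Both are scaled by the specimen's
    centroid size (pointing error is proportional to the rendered size).
    Output specimen ids are suffixed with the user id; ``individual_id``
    keeps the source specimen's identity.
    """
    rng = np.random.default_rng(seed)
    offsets = rng.normal(scale=delta_persistent, size=(dataset.landmark_count, 2)) if delta_persistent > 0 else np.zeros((dataset.landmark_count, 2))
    configs = []
    for c in dataset:
        cs = centroid_size(c)
        noise = rng.normal(scale=sigma_point, size=c.coords.shape) if sigma_point > 0 else 0.0
        xy = c.coords + cs * offsets + cs * noise
        configs.append(
            c.with_coords(
                xy,
                specimen_id=f"{c.specimen_id}:{user_id}",
                individual_id=c.individual_id,
                user_id=user_id,
            )
        )
    return LandmarkDataset(configs, provenance=dataset.provenance + f" + user({user_id})")


def simulate_replicates(
    dataset: LandmarkDataset, n_replicates: int, sigma_point: float, seed: int
) -> LandmarkDataset:
    """Replicated digitization sessions of every specimen.

    Each specimen is duplicated ``n_replicates`` times with independent
    pointing noise (SD ``sigma_point``, scaled by centroid size); replicate
    ids are attached and ``individual_id`` records the source specimen, so
    the result feeds straight into the repeatability ANOVA.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    configs = []
    for c in dataset:
        cs = centroid_size(c)
        for r in range(1, n_replicates + 1):
            noise = rng.normal(scale=sigma_point, size=c.coords.shape) if sigma_point > 0 else 0.0
            configs.append(
                c.with_coords(
                    c.coords + cs * noise,
                    specimen_id=f"{c.specimen_id}:r{r}",
                    individual_id=c.individual_id,
                    replicate_id=f"r{r}",
                )
            )
    return LandmarkDataset(configs, provenance=dataset.provenance + f" x{n_replicates} replicates")


def simulate_user_study(
    dataset: LandmarkDataset,
    user_specs: list[dict],
    n_replicates: int = 2,
    seed: int = 0,
) -> LandmarkDataset:
    """Digitization of one specimen set by several users, with replicates.

    Each user spec is a dict with ``user_id``, ``delta_persistent`` and
    ``sigma_point``.  Every user digitizes every specimen ``n_replicates``
    times: the user's persistent offset is applied once, then independent
    pointing noise per replicate session.  The merged dataset (unique ids,
    ``individual_id`` tying digitizations of the same specimen together)
    feeds directly into repeatability_anova / compare_users.
    """
    from .landmark_io import merge_datasets

    rng = np.random.default_rng(seed)
    parts = []
    for spec in user_specs:
        s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
        uid = spec["user_id"]
        delta = spec.get("delta_persistent", 0.0)
        sigma = spec.get("sigma_point", 0.0)
        if n_replicates >= 2:
            biased = apply_user_effect(dataset, uid, delta, 0.0, s1)
            parts.append(simulate_replicates(biased, n_replicates, sigma, s2))
        else:
            parts.append(apply_user_effect(dataset, uid, delta, sigma, s1))
    return merge_datasets(*parts)


def simulate_digitization_designs(
    dataset: LandmarkDataset,
    delta_persistent: float,
    sigma_point: float,
    seed: int,
) -> tuple[LandmarkDataset, LandmarkDataset, LandmarkDataset]:
    """One-user vs two-user versions of the reference-bank exchange scenario.

    Returns ``(references, one_user_queries, two_user_queries)``.  The
    reference coordinates are user u1's digitizations of every specimen.
    The queries are a second, independent digitization of the same
    specimens: by u1 again (one-user design), or by u2 (two-user design),
    whose digitization is the *same* pointing-noise realization plus u2's
    persistent per-landmark offset — so the two designs are compared on
    identical randomness and differ only in who digitized the queries,
    which is the comparison behind the published one-user/two-user error
    tables.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    references = apply_user_effect(dataset, "u1", 0.0, sigma_point, s1)
    one_user = apply_user_effect(dataset, "u1", 0.0, sigma_point, s2)
    one_user = LandmarkDataset(
        [
            c.with_coords(c.coords, specimen_id=c.specimen_id + ":q")
            for c in one_user.configurations
        ],
        provenance=dataset.provenance + " + one-user queries",
    )
    offsets = rng.normal(scale=delta_persistent, size=(dataset.landmark_count, 2))
    two_user = LandmarkDataset(
        [
            c.with_coords(
                c.coords + centroid_size(c) * offsets,
                specimen_id=c.individual_id + ":u2:q",
                user_id="u2",
            )
            for c in one_user.configurations
        ],
        provenance=dataset.provenance + " + two-user queries",
    )
    return references, one_user, two_user


def bayes_error_oracle(
    separation: float, sigma: float, dim: int, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo Bayes error of the planted two-species tangent model.

    Two isotropic Gaussians in ``dim``-dimensional tangent space, per-axis
    SD ``sigma``, means ``separation`` apart; the Bayes rule is assignment
    to the nearer true mean.  Returns the misclassification probability
    estimated from ``n_draws`` draws (closed forms are unavailable for the
    post-superimposition pipeline, so the oracle stays a simulation).
    """
    rng = np.random.default_rng(seed)
    m1 = np.zeros(dim)
    m2 = np.zeros(dim)
    m2[0] = separation
    x = m1 + rng.normal(scale=sigma, size=(n_draws, dim))
    wrong = ((x - m2) ** 2).sum(axis=1) < ((x - m1) ** 2).sum(axis=1)
    return float(wrong.mean())


def generate_scenario(scenario: SimulationScenario) -> dict:
    """Run a full scenario: template -> means -> specimens -> users/replicates.

    Returns a dict with the template, species means, the clean specimen
    dataset, one digitized dataset per user spec (or the clean dataset under
    key 'digitized' when no users are specified), and a ground-truth table.
    """
    rng = np.random.default_rng(scenario.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    template = make_template(scenario.k, scenario.template)
    means = simulate_species_means(template, scenario.n_species, scenario.separation, sub[0])
    specimens = simulate_specimens(means, scenario.n_per_species, scenario.sigma_shape, sub[1])

    out: dict = {"template": template, "means": means, "specimens": specimens}
    digitized: dict[str, LandmarkDataset] = {}
    for i, spec in enumerate(scenario.user_specs):
        ds = apply_user_effect(
            specimens,
            user_id=spec["user_id"],
            delta_persistent=spec.get("delta_persistent", 0.0),
            sigma_point=spec.get("sigma_point", 0.0),
            seed=sub[2] + i,
        )
        if scenario.n_replicates >= 2:
            ds = simulate_replicates(
                ds, scenario.n_replicates, spec.get("sigma_point", 0.0), sub[3] + i
            )
        digitized[spec["user_id"]] = ds
    out["digitized"] = digitized

    truth_rows = [
        {
            "specimen_id": c.specimen_id,
            "species": c.species,
            "separation": scenario.separation,
            "sigma_shape": scenario.sigma_shape,
        }
        for c in specimens
    ]
    out["truth"] = pd.DataFrame(truth_rows)
    return out
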