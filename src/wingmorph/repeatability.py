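"""Measurement error and the user effect: ANOVA repeatability and
session-to-session distance scatter.

Repeatability R of a variable is the fraction of its total variance
attributable to true among-individual differences rather than digitization
error, estimated from a one-way ANOVA with individuals as groups:

    s2_among = (MS_among - MS_within) / n0,
    R = s2_among / (s2_among + MS_within),

where n0 is the replicates-per-individual coefficient (equal to r for a
balanced design, and ``(N - sum(n_i^2)/N) / (a - 1)`` otherwise).  Negative
among-individual variance estimates are truncated at zero, keeping R in
[0, 1].  Variables are by default the partial-warp scores from one joint
GPA over all digitizations (the same space classification uses); raw
aligned coordinates are available as an option.  Per-variable R values are
summarized as mean ± SD across variables.

The user effect — two people digitizing the same specimens — is quantified
by comparing each user's own-replicate R with the R obtained when the two
users' digitizations are treated as replicates of one another, and
visualized by the scatter of pairwise Procrustes distances measured twice
(same user vs different users) around the identity line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkDataset
from .shape_variables import partial_warps
from .superimposition import distance_matrix, gpa

__all__ = [
    "RepeatabilityResult",
    "PairedRepeatability",
    "SessionScatter",
    "repeatability_anova",
    "compare_users",
    "session_scatter",
]


@dataclass
class RepeatabilityResult:
    """Per-variable and summary repeatability of one replication design."""

    per_variable_R: list[tuple[str, float]]
    mean_R: float
    sd_R: float
    design: str  # "one_user" | "two_users"
    n_individuals: int
    n_replicates: float  # r, or the n0 coefficient for unbalanced designs
    variable_kind: str  # "partial_warps" | "coordinates"

    def summary(self) -> str:
        return f"{self.mean_R:.4f} ± {self.sd_R:.4f}"

    def to_rows(self) -> list[dict]:
        return [{"variable": v, "R": r} for v, r in self.per_variable_R]


def _anova_R(values: np.ndarray, individuals: np.ndarray) -> float:
    """One-way ANOVA repeatability of a single variable."""
    groups = [values[individuals == ind] for ind in np.unique(individuals)]
    a = len(groups)
    N = values.shape[0]
    sizes = np.array([len(g) for g in groups])
    grand = values.mean()
    ss_among = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - (sizes**2).sum() / N) / (a - 1)
    s2_among = max((ms_among - ms_within) / n0, 0.0)
    denom = s2_among + ms_within
    if denom == 0.0:
        return 1.0  # replicates exactly identical across the board
    return float(np.clip(s2_among / denom, 0.0, 1.0))


def _variables(dataset: LandmarkDataset, variable_kind: str) -> tuple[np.ndarray, list[str]]:
    res = gpa(dataset)
    if variable_kind == "partial_warps":
        pw = partial_warps(res)
        return pw.scores, pw.column_names
    if variable_kind == "coordinates":
        X = res.aligned.reshape(res.n, -1)
        names = [f"{ax}{i + 1}" for i in range(res.k) for ax in ("x", "y")]
        return X, names
    raise ValueError(f"unknown variable_kind {variable_kind!r}")


def repeatability_anova(
    dataset: LandmarkDataset, variable_kind: str = "partial_warps", design: str | None = None
) -> RepeatabilityResult:
    """ANOVA repeatability of replicated digitizations.

    ``dataset`` must contain >= 2 individuals (grouped by ``individual_id``),
    each digitized >= 2 times.  All digitizations enter one joint GPA; R is
    then estimated per shape variable and summarized across variables.
    """
    individuals = np.array([c.individual_id for c in dataset.configurations])
    uniq, counts = np.unique(individuals, return_counts=True)
    if uniq.size < 2:
        raise ValueError("repeatability needs >= 2 individuals")
    if counts.min() < 2:
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"every individual needs >= 2 replicate digitizations; single: {bad}")

    X, names = _variables(dataset, variable_kind)
    Rs = [(name, _anova_R(X[:, j], individuals)) for j, name in enumerate(names)]
    r_values = np.array([r for _, r in Rs])
    N = individuals.size
    n0 = (N - (counts**2).sum() / N) / (uniq.size - 1)
    if design is None:
        users = {c.user_id for c in dataset.configurations if c.user_id is not None}
        design = "two_users" if len(users) > 1 else "one_user"
    return RepeatabilityResult(
        per_variable_R=Rs,
        mean_R=float(r_values.mean()),
        sd_R=float(r_values.std(ddof=1)) if r_values.size > 1 else 0.0,
        design=design,
        n_individuals=int(uniq.size),
        n_replicates=float(n0),
        variable_kind=variable_kind,
    )


@dataclass
class PairedRepeatability:
    """One-user repeatabilities (per user) against the pooled two-user one."""

    per_user: dict[str, RepeatabilityResult]
    pooled: RepeatabilityResult
    dropped_individuals: list[str] = field(default_factory=list)

    @property
    def one_user_mean_R(self) -> float:
        return float(np.mean([r.mean_R for r in self.per_user.values()]))

    @property
    def two_user_mean_R(self) -> float:
        return self.pooled.mean_R

    @property
    def difference(self) -> float:
        """one-user minus two-user mean R (positive under a user effect)."""
        return self.one_user_mean_R - self.two_user_mean_R


def compare_users(
    dataset: LandmarkDataset, variable_kind: str = "partial_warps"
) -> PairedRepeatability:
    """Quantify the user effect on repeatability.

    Expects every individual digitized by both users (optionally several
    times each).  One-user R is estimated within each user's own replicates
    (users with a single digitization per individual are skipped with a
    warning); two-user R treats the two users' digitizations of an
    individual as replicates of one another.  Individuals missing one
    user's digitization are dropped with a warning.
    """
    users = sorted({c.user_id for c in dataset.configurations if c.user_id is not None})
    if len(users) != 2:
        raise ValueError(f"compare_users expects exactly 2 user labels, found {users}")

    by_ind: dict[str, set] = {}
    for c in dataset.configurations:
        by_ind.setdefault(c.individual_id, set()).add(c.user_id)
    complete = {ind for ind, us in by_ind.items() if set(users) <= us}
    dropped = sorted(set(by_ind) - complete)
    if dropped:
        warnings.warn(
            f"{len(dropped)} individual(s) missing one user's digitization were dropped",
            stacklevel=2,
        )
    configs = [c for c in dataset.configurations if c.individual_id in complete]
    pooled_ds = LandmarkDataset(configs, provenance=dataset.provenance)

    per_user: dict[str, RepeatabilityResult] = {}
    for user in users:
        own = [c for c in configs if c.user_id == user]
        counts = np.unique([c.individual_id for c in own], return_counts=True)[1]
        if counts.min() < 2:
            warnings.warn(
                f"user {user!r} digitized some individuals only once; "
                "one-user repeatability unavailable for this user",
                stacklevel=2,
            )
            continue
        per_user[user] = repeatability_anova(
            LandmarkDataset(own), variable_kind=variable_kind, design="one_user"
        )
    pooled = repeatability_anova(pooled_ds, variable_kind=variable_kind, design="two_users")
    return PairedRepeatability(per_user=per_user, pooled=pooled, dropped_individuals=dropped)


@dataclass
class SessionScatter:
    """Matched pairwise distances from two digitization sessions.

    The diagnostic behind the distance-scatter plot: pairwise Procrustes
    distances among the same specimens, evaluated twice; deviations from the
    identity line measure how measurement error propagates into the final
    distances.  ``rms_deviation_from_identity`` is the root-mean-square
    perpendicular distance of the (d1, d2) points to the identity line.
    """

    pair_ids: list[tuple[str, str]]
    distances_session1: np.ndarray
    distances_session2: np.ndarray
    correlation: float
    rms_deviation_from_identity: float

    def to_rows(self) -> list[dict]:
        return [
            {"id_a": a, "id_b": b, "d_session1": float(d1), "d_session2": float(d2)}
            for (a, b), d1, d2 in zip(
                self.pair_ids, self.distances_session1, self.distances_session2
            )
        ]

    def plot(self, ax=None):
        """Scatter of session-2 vs session-1 distances with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.distances_session1, self.distances_session2, "*", ms=4)
        lim = max(self.distances_session1.max(), self.distances_session2.max()) * 1.05
        ax.plot([0, lim], [0, lim], "k-", lw=0.8)
        ax.set_xlabel("pairwise Procrustes distance, session 1")
        ax.set_ylabel("pairwise Procrustes distance, session 2")
        return ax


def session_scatter(
    session1: LandmarkDataset, session2: LandmarkDataset, variant: str = "partial"
) -> SessionScatter:
    """Compare pairwise Procrustes distances measured in two sessions.

    Sessions must contain the same individuals (matched by ``individual_id``);
    an id mismatch raises with the unmatched ids listed.
    """
    ids1 = {c.individual_id: c for c in session1.configurations}
    ids2 = {c.individual_id: c for c in session2.configurations}
    if len(ids1) != len(session1) or len(ids2) != len(session2):
        raise ValueError("each session must contain one digitization per individual")
    only1 = sorted(set(ids1) - set(ids2))
    only2 = sorted(set(ids2) - set(ids1))
    if only1 or only2:
        raise ValueError(
            f"session individual ids do not match; only in session1: {only1}, "
            f"only in session2: {only2}"
        )
    order = sorted(ids1)
    ds1 = LandmarkDataset([ids1[i].with_coords(ids1[i].coords, specimen_id=i) for i in order])
    ds2 = LandmarkDataset([ids2[i].with_coords(ids2[i].coords, specimen_id=i) for i in order])
    D1 = distance_matrix(ds1, variant=variant).values
    D2 = distance_matrix(ds2, variant=variant).values
    iu = np.triu_indices(len(order), k=1)
    d1, d2 = D1[iu], D2[iu]
    pair_ids = [(order[i], order[j]) for i, j in zip(*iu)]
    if np.std(d1) == 0 or np.std(d2) == 0:
        corr = 1.0 if np.allclose(d1, d2) else 0.0
    else:
        corr = float(np.corrcoef(d1, d2)[0, 1])
    rms = float(np.sqrt(np.mean((d1 - d2) ** 2) / 2.0))
    return SessionScatter(
        pair_ids=pair_ids,
        distances_session1=d1,
        distances_session2=d2,
        correlation=corr,
        rms_deviation_from_identity=rms,
    )
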