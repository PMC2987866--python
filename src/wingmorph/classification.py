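"""Assigning unknown specimens to reference species.

Two classifiers are provided, mirroring the two distance families used in
landmark-based species identification:

* **Procrustes classification** — each unknown is compared by Procrustes
  distance with the consensus (mean shape) of every reference species
  (``nearest_consensus``), or with every reference individual separately
  (``nearest_individual``), and assigned to the species with the shortest
  distance.  No account is taken of the dispersion ellipses of the groups.

* **Mahalanobis classification** — canonical variate analysis on shape
  variables, with distances standardized by the pooled within-group
  covariance.  The *one-by-one* protocol is mandatory: for each unknown
  separately, a GPA is run over the references plus that single unknown,
  shape variables are computed relative to that joint consensus, the
  discriminant model is fitted on the reference rows exclusively, and the
  unknown is projected in as supplementary data.  Entering many unknowns at
  once would shift the consensus and degrade the discrimination between
  references, so batch processing is never performed.

Assignment always uses the shortest distance; assignment is discrimination,
not identification — the shortest distance may still be large, so each
record carries an ``outlier_flag`` raised when the unknown lies beyond the
95th percentile of the winning group's own member-to-center distances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from .exceptions import ShapeMismatchError, SingularityError
from .landmark_io import LandmarkConfiguration, LandmarkDataset
from .shape_variables import ShapeVariables, consensus_hash, partial_warps, relative_warps
from .superimposition import gpa, preshape, procrustes_distance

__all__ = [
    "DiscriminantModel",
    "ClassificationRecord",
    "ClassificationReport",
    "procrustes_classify",
    "fit_cva",
    "mahalanobis_distance",
    "classify_one_by_one",
    "loo_errors",
]

_TIE_TOL = 1e-9
_OUTLIER_PERCENTILE = 95.0


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------


@dataclass
class ClassificationRecord:
    specimen_id: str
    method: str  # "procrustes" | "mahalanobis"
    assigned_group: str
    distance_to_each_group: dict[str, float]
    distance_to_nearest_reference_individual: float | None = None
    outlier_flag: bool = False
    tie_flag: bool = False
    converged: bool = True
    true_group: str | None = None

    @property
    def correct(self) -> bool | None:
        if self.true_group is None:
            return None
        return self.assigned_group == self.true_group


@dataclass
class ClassificationReport:
    """Per-specimen assignments plus the per-group error table.

    The error table (available when unknowns carry true labels) lists, per
    reference species and in total, cells formatted ``misassigned/total
    (percent)`` with integer-rounded percentages.
    """

    records: list[ClassificationRecord]
    method: str
    params: dict = field(default_factory=dict)
    validation_design: str | None = None  # e.g. "leave-one-out"

    def assignments(self) -> dict[str, str]:
        return {r.specimen_id: r.assigned_group for r in self.records}

    def error_counts(self) -> dict[str, tuple[int, int]] | None:
        """Per-true-group (misassigned, total) counts; None when no truth."""
        scored = [r for r in self.records if r.true_group is not None]
        if not scored:
            return None
        counts: dict[str, list[int]] = {}
        for r in scored:
            c = counts.setdefault(r.true_group, [0, 0])
            c[1] += 1
            if not r.correct:
                c[0] += 1
        return {g: (c[0], c[1]) for g, c in sorted(counts.items())}

    @property
    def total_errors(self) -> tuple[int, int] | None:
        counts = self.error_counts()
        if counts is None:
            return None
        mis = sum(m for m, _ in counts.values())
        tot = sum(t for _, t in counts.values())
        return mis, tot

    @property
    def total_error_rate(self) -> float | None:
        te = self.total_errors
        if te is None or te[1] == 0:
            return None
        return te[0] / te[1]

    def error_table_text(self) -> str:
        """Human-readable error table: one row per species, 'x/n (p%)' cells."""
        counts = self.error_counts()
        if counts is None:
            return "no true labels supplied; error table unavailable"
        width = max(len(g) for g in counts) if counts else 8
        lines = [f"{'Species':<{width}}  Distances    Errors"]
        for g, (m, t) in counts.items():
            lines.append(f"{g:<{width}}  {self.method:<11}  {_cell(m, t)}")
        m, t = self.total_errors
        lines.append(f"{'Total errors':<{width}}  {self.method:<11}  {_cell(m, t)}")
        if self.validation_design:
            lines.append(f"(validation design: {self.validation_design})")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "params": {k: _jsonable(v) for k, v in self.params.items()},
            "validation_design": self.validation_design,
            "records": [
                {
                    "specimen_id": r.specimen_id,
                    "assigned_group": r.assigned_group,
                    "true_group": r.true_group,
                    "distances": {g: float(d) for g, d in r.distance_to_each_group.items()},
                    "nearest_reference_individual": r.distance_to_nearest_reference_individual,
                    "outlier": r.outlier_flag,
                    "tie": r.tie_flag,
                    "converged": r.converged,
                }
                for r in self.records
            ],
            "error_counts": {
                g: {"misassigned": m, "total": t, "percent": round(100 * m / t)}
                for g, (m, t) in (self.error_counts() or {}).items()
            },
        }
        if self.total_errors is not None:
            m, t = self.total_errors
            payload["total_errors"] = {"misassigned": m, "total": t, "percent": round(100 * m / t)}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _cell(m: int, t: int) -> str:
    return f"{m}/{t} ({round(100 * m / t)}%)"


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def _assign(distances: dict[str, float]) -> tuple[str, bool]:
    """Shortest-distance assignment; lexicographic tie-break, tie flagged."""
    d_min = min(distances.values())
    tied = sorted(g for g, d in distances.items() if d - d_min <= _TIE_TOL * max(1.0, d_min))
    return tied[0], len(tied) > 1


# ---------------------------------------------------------------------------
# Procrustes classification
# ---------------------------------------------------------------------------


def procrustes_classify(
    references: LandmarkDataset,
    unknowns: LandmarkDataset,
    rule: str = "nearest_consensus",
    variant: str = "partial",
) -> ClassificationReport:
    """Assign each unknown to the species with the shortest Procrustes distance.

    ``nearest_consensus`` compares each unknown with the GPA mean shape of
    every reference species; ``nearest_individual`` compares with every
    reference specimen separately and scores each species by its closest
    member.  Both distance sets are reported either way.
    """
    if rule not in ("nearest_consensus", "nearest_individual"):
        raise ValueError(f"unknown rule {rule!r}")
    refs = references.references()
    if refs.landmark_count != unknowns.landmark_count:
        raise ShapeMismatchError(
            f"references have k={refs.landmark_count}, unknowns k={unknowns.landmark_count}"
        )
    groups = refs.by_species()
    if len(groups) < 2:
        raise ValueError("Procrustes classification needs >= 2 reference species")

    consensuses: dict[str, LandmarkConfiguration] = {}
    internal: dict[str, np.ndarray] = {}  # member-to-consensus distances
    for species, grp in groups.items():
        if len(grp) == 1:
            warnings.warn(
                f"species {species!r} has a single reference specimen; "
                "its consensus degenerates to that specimen",
                stacklevel=2,
            )
            consensuses[species] = preshape(grp[0])
            internal[species] = np.array([0.0])
        else:
            res = gpa(grp)
            consensuses[species] = res.consensus_configuration()
            internal[species] = np.array(
                [procrustes_distance(a, res.consensus, variant) for a in res.aligned]
            )

    records = []
    for u in unknowns:
        d_cons = {s: procrustes_distance(u, c, variant) for s, c in consensuses.items()}
        d_near: dict[str, float] = {
            s: min(procrustes_distance(u, r, variant) for r in grp)
            for s, grp in groups.items()
        }
        scores = d_cons if rule == "nearest_consensus" else d_near
        assigned, tie = _assign(scores)
        thresh = float(np.percentile(internal[assigned], _OUTLIER_PERCENTILE))
        records.append(
            ClassificationRecord(
                specimen_id=u.specimen_id,
                method="procrustes",
                assigned_group=assigned,
                distance_to_each_group=dict(scores),
                distance_to_nearest_reference_individual=float(min(d_near.values())),
                outlier_flag=bool(d_cons[assigned] > thresh),
                tie_flag=tie,
                true_group=u.species,
            )
        )
    return ClassificationReport(records=records, method="procrustes", params={"rule": rule, "variant": variant})


# ---------------------------------------------------------------------------
# Canonical variate analysis / Mahalanobis classification
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantModel:
    """CVA model fitted on reference shape variables exclusively.

    Mahalanobis distances are Euclidean distances in the space whitened by
    the pooled within-group covariance; ``discriminant_axes`` (up to g-1)
    give the canonical variates for ordination.  ``consensus_id`` records
    which consensus the input shape variables were relative to, so scores
    from another superimposition cannot be projected in silently.
    """

    group_labels: list[str]
    group_means: np.ndarray  # (g, m)
    pooled_within_covariance: np.ndarray  # (m, m)
    discriminant_axes: np.ndarray  # (m, <=g-1)
    training_ids: list[str]
    input_kind: str
    consensus_id: str
    ridge: float = 0.0
    _chol: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._chol is None:
            self._chol = cho_factor(self.pooled_within_covariance)

    @property
    def g(self) -> int:
        return len(self.group_labels)

    @property
    def m(self) -> int:
        return self.group_means.shape[1]


def fit_cva(
    shape_vars: ShapeVariables,
    labels=None,
    retain: int | float | None = None,
    ridge: float = 0.0,
) -> DiscriminantModel:
    """Fit a canonical variate analysis on labeled shape-variable rows.

    ``labels`` defaults to the species labels carried by ``shape_vars``;
    rows with a None label are excluded (they are not references).  With
    ``retain`` set and partial-warp input, relative warps are computed first
    and the requested number/fraction of axes kept.  ``ridge`` adds
    ``ridge * trace(S_w)/m`` to the pooled within-group covariance diagonal
    for small-sample stabilization (default 0: a singular covariance raises
    rather than being silently pseudo-inverted).
    """
    if labels is None:
        labels = shape_vars.labels
    if labels is None:
        raise ValueError("labels are required (none stored on the shape variables)")
    labels = list(labels)
    if len(labels) != shape_vars.n:
        raise ValueError(f"{len(labels)} labels for {shape_vars.n} score rows")

    sv = shape_vars
    if retain is not None and sv.kind == "partial_warps":
        sv = relative_warps(sv, retain=retain)
    X = sv.scores
    ids = sv.specimen_ids

    keep = [i for i, lab in enumerate(labels) if lab is not None]
    X = X[keep]
    ids = [ids[i] for i in keep]
    y = np.array([labels[i] for i in keep])
    groups = sorted(set(y))
    if len(groups) < 2:
        raise ValueError("CVA needs at least 2 groups")
    n, m = X.shape
    g = len(groups)
    if n - g < 1:
        raise SingularityError("not enough reference specimens to estimate within-group scatter")

    means = np.vstack([X[y == grp].mean(axis=0) for grp in groups])
    W = np.zeros((m, m))
    for i, grp in enumerate(groups):
        R = X[y == grp] - means[i]
        W += R.T @ R
    Sw = W / (n - g)
    if ridge > 0:
        Sw = Sw + (ridge * np.trace(Sw) / m) * np.eye(m)

    # fail loudly on a singular pooled covariance
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularityError(
            f"pooled within-group covariance is singular (cond={cond:.2e}); "
            "lower the retained dimension below n - g or set ridge > 0"
        )

    # between-group scatter (weighted by group sizes)
    grand = X.mean(axis=0)
    Sb = np.zeros((m, m))
    for i, grp in enumerate(groups):
        d = (means[i] - grand)[:, None]
        Sb += (y == grp).sum() * (d @ d.T)
    Sb /= max(n - 1, 1)
    evals, evecs = eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][: g - 1]
    axes = evecs[:, order]

    return DiscriminantModel(
        group_labels=groups,
        group_means=means,
        pooled_within_covariance=Sw,
        discriminant_axes=axes,
        training_ids=ids,
        input_kind=f"{sv.kind}[{sv.m}]",
        consensus_id=sv.consensus_id,
        ridge=ridge,
    )


def mahalanobis_distance(model: DiscriminantModel, score_row: np.ndarray, group: str) -> float:
    """Mahalanobis distance of a score row to a group mean.

    ``sqrt((x - mu_g)' S_w^-1 (x - mu_g))`` with the pooled within-group
    covariance; zero iff the row equals the group mean.
    """
    if group not in model.group_labels:
        raise ValueError(f"unknown group {group!r}")
    x = np.asarray(score_row, dtype=float).reshape(-1)
    if x.shape[0] != model.m:
        raise ValueError(f"score row has dimension {x.shape[0]}, model expects {model.m}")
    d = x - model.group_means[model.group_labels.index(group)]
    return float(np.sqrt(max(d @ cho_solve(model._chol, d), 0.0)))


def _mahalanobis_all(model: DiscriminantModel, x: np.ndarray) -> dict[str, float]:
    return {g: mahalanobis_distance(model, x, g) for g in model.group_labels}


def _resolve_retain(retain, n_refs: int, g: int):
    """Default retention: RW axes explaining 95% variance, capped at n-g-1."""
    cap = max(n_refs - g - 1, 1)
    if retain is None:
        return ("auto95", cap)
    return (retain, cap)


def _classify_single(
    references: LandmarkDataset,
    unknown: LandmarkConfiguration,
    retain,
    ridge: float,
    include_uniform: bool,
) -> ClassificationRecord:
    """One round of the one-by-one protocol for a single unknown."""
    uid = unknown.specimen_id
    if uid in set(references.specimen_ids):
        uid = uid + ":unknown"
    u = unknown.with_coords(unknown.coords, specimen_id=uid, species=None)
    joint = LandmarkDataset(list(references.configurations) + [u])
    res = gpa(joint)
    pw = partial_warps(res, include_uniform=include_uniform)

    ref_labels = [c.species for c in references.configurations] + [None]
    spec_retain, cap = _resolve_retain(retain, len(references), len(set(x for x in ref_labels if x)))
    if spec_retain == "auto95":
        rw_all = relative_warps(pw, retain=0.95)
        if rw_all.m > cap:
            rw_all = relative_warps(pw, retain=cap)
    else:
        rw_all = relative_warps(pw, retain=spec_retain)

    model = fit_cva(rw_all, labels=ref_labels, ridge=ridge)
    x_u = rw_all.scores[-1]
    dists = _mahalanobis_all(model, x_u)
    assigned, tie = _assign(dists)

    # internal Mahalanobis distances of the winning group's own members
    y = np.array(ref_labels[:-1], dtype=object)
    members = rw_all.scores[:-1][y == assigned]
    internal = np.array([mahalanobis_distance(model, row, assigned) for row in members])
    thresh = float(np.percentile(internal, _OUTLIER_PERCENTILE)) if internal.size else np.inf

    return ClassificationRecord(
        specimen_id=unknown.specimen_id,
        method="mahalanobis",
        assigned_group=assigned,
        distance_to_each_group=dists,
        outlier_flag=bool(dists[assigned] > thresh),
        tie_flag=tie,
        converged=res.converged,
        true_group=unknown.species,
    )


def classify_one_by_one(
    references: LandmarkDataset,
    unknowns: LandmarkDataset,
    retain=None,
    ridge: float = 0.0,
    include_uniform: bool = True,
) -> ClassificationReport:
    """Mahalanobis classification via the mandatory one-by-one protocol.

    Every unknown is processed independently: GPA over the references plus
    that single unknown, shape variables relative to the joint consensus,
    CVA fitted on the reference rows exclusively, then the unknown projected
    in and assigned to the group at the shortest Mahalanobis distance.
    Assignments therefore do not depend on the order or composition of the
    unknown set.
    """
    refs = references.references()
    if refs.landmark_count != unknowns.landmark_count:
        raise ShapeMismatchError(
            f"references have k={refs.landmark_count}, unknowns k={unknowns.landmark_count}"
        )
    records = [_classify_single(refs, u, retain, ridge, include_uniform) for u in unknowns]
    return ClassificationReport(
        records=records,
        method="mahalanobis",
        params={"retain": retain if retain is not None else "auto95", "ridge": ridge,
                "protocol": "one-by-one"},
    )


# ---------------------------------------------------------------------------
# Leave-one-out error tables
# ---------------------------------------------------------------------------


def loo_errors(
    references: LandmarkDataset,
    method: str = "mahalanobis",
    retain=None,
    ridge: float = 0.0,
    rule: str = "nearest_consensus",
    query_replicates: LandmarkDataset | None = None,
) -> ClassificationReport:
    """Leave-one-out assignation-error table over the reference set.

    Each reference specimen is removed in turn, treated as the single
    unknown through the chosen protocol, and scored against its true label.
    Species with a single specimen are excluded with a warning.  The report
    carries per-species and total 'misassigned/total (percent)' counts.

    With ``query_replicates`` the held-out specimen enters not as its own
    reference digitization but as an independent re-digitization of the same
    individual (matched by ``individual_id``) — the design for measuring how
    digitization error, e.g. a second user's, degrades identification.
    """
    if method not in ("procrustes", "mahalanobis"):
        raise ValueError(f"unknown method {method!r}")
    refs = references.references()
    groups = refs.by_species()
    usable = [s for s, grp in groups.items() if len(grp) >= 2]
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        warnings.warn(f"species with a single specimen excluded from LOO: {skipped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("LOO needs >= 2 species with >= 2 specimens each")

    pool = LandmarkDataset(
        [c for c in refs.configurations if c.species in usable], provenance=refs.provenance
    )
    by_individual = None
    if query_replicates is not None:
        by_individual = {c.individual_id: c for c in query_replicates.configurations}
        missing = [c.individual_id for c in pool if c.individual_id not in by_individual]
        if missing:
            raise ValueError(f"query_replicates lack digitizations for individuals {missing}")

    records = []
    for held in pool:
        rest = LandmarkDataset(
            [c for c in pool.configurations if c.specimen_id != held.specimen_id]
        )
        if by_individual is None:
            query = held
        else:
            rep_cfg = by_individual[held.individual_id]
            query = rep_cfg.with_coords(rep_cfg.coords, species=held.species)
        if method == "procrustes":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = procrustes_classify(rest, LandmarkDataset([query]), rule=rule)
            records.append(rep.records[0])
        else:
            records.append(_classify_single(rest, query, retain, ridge, True))
    return ClassificationReport(
        records=records,
        method=method,
        params={"retain": retain if retain is not None else "auto95", "ridge": ridge, "rule": rule},
        validation_design="leave-one-out"
        + ("" if query_replicates is None else " (re-digitized queries)"),
    )
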