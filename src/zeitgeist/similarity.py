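"""Pairwise and participant-to-reference similarity measures.

Builds the long-format dyad tables the mixed models consume: one row per
unordered pair of participants per target, with the pair's similarity and
pair-level predictors (the pair-mean loneliness score of the Anna Karenina
model, demographic match codes, z-scored-and-sign-flipped dissimilarity
covariates).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PatternMatrix",
    "pairwise_similarity",
    "to_distance",
    "similarity_to_reference",
    "mean_pair_predictor",
    "build_dyad_covariates",
]

METRICS = ("pearson", "cosine", "jaccard")


class PatternMatrix:
    """Participants x features matrix for one target.

    Parameters
    ----------
    values : (n_participants, n_features) array; NaN marks missing entries
        (allowed only in the ``trait_binary`` space).
    participant_ids : unique identifiers, one per row.
    target_id : label of the represented target.
    space : one of ``neural``, ``embedding``, ``trait_binary``, ``rating``.
    """

    SPACES = ("neural", "embedding", "trait_binary", "rating")

    def __init__(self, values, participant_ids, target_id, space="neural"):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] < 2:
            raise ValueError("values must be 2-D with >= 2 features")
        participant_ids = list(participant_ids)
        if len(participant_ids) != values.shape[0]:
            raise ValueError("participant_ids length mismatch")
        if len(set(participant_ids)) != len(participant_ids):
            raise ValueError("duplicate participant ids")
        if space not in self.SPACES:
            raise ValueError(f"space must be one of {self.SPACES}")
        if space == "trait_binary":
            vals = values[~np.isnan(values)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("trait_binary entries must be 0, 1 or missing")
        elif np.isnan(values).any():
            raise ValueError(f"missing entries not allowed in space {space!r}")
        self.values = values
        self.participant_ids = participant_ids
        self.target_id = target_id
        self.space = space

    @property
    def n_participants(self):
        return self.values.shape[0]

    @property
    def n_features(self):
        return self.values.shape[1]


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def _cosine(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def _jaccard(a, b):
    """Jaccard on positive responses after pairwise deletion of missing."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return np.nan
    a, b = a[ok] > 0.5, b[ok] > 0.5
    union = np.sum(a | b)
    if union == 0:
        # both all-zero over the shared features: identical responses
        return 1.0
    return float(np.sum(a & b) / union)


_PAIR_FUNCS = {"pearson": _pearson, "cosine": _cosine, "jaccard": _jaccard}


def pairwise_similarity(patterns: PatternMatrix, metric="pearson") -> pd.DataFrame:
    """Similarity for every unordered pair of participants.

    Returns a dyad table with columns ``participant1``, ``participant2``,
    ``target``, ``similarity`` and ``flag_undefined``.  Undefined rows
    (zero-variance vector under Pearson, empty missing-data overlap under
    Jaccard) carry NaN similarity and a raised flag rather than a silent 0.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric == "jaccard" and patterns.space != "trait_binary":
        raise ValueError("jaccard requires trait_binary patterns")
    if metric != "jaccard" and patterns.space == "trait_binary":
        logger.info("correlation metric applied to binary patterns")
    func = _PAIR_FUNCS[metric]
    vals = patterns.values
    ids = patterns.participant_ids
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        s = func(vals[i], vals[j])
        rows.append((ids[i], ids[j], patterns.target_id, s, np.isnan(s)))
    df = pd.DataFrame(rows, columns=["participant1", "participant2",
                                     "target", "similarity", "flag_undefined"])
    n_bad = int(df.flag_undefined.sum())
    if n_bad:
        logger.warning("%d undefined %s similarities flagged", n_bad, metric)
    return df


def to_distance(similarity) -> np.ndarray | pd.DataFrame:
    """Correlation/cosine distance, ``1 - similarity``.

    Accepts either a square similarity matrix (returns a distance matrix
    with a forced zero diagonal) or a dyad table (returns a copy with a
    ``distance`` column).
    """
    if isinstance(similarity, pd.DataFrame):
        if similarity.get("flag_undefined", pd.Series(False)).any():
            raise ValueError("undefined similarity rows cannot be converted")
        out = similarity.copy()
        out["distance"] = 1.0 - out["similarity"]
        return out
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("expected a square similarity matrix")
    if np.isnan(sim).any():
        raise ValueError("undefined similarities present")
    dist = 1.0 - sim
    # similarities can exceed 1 by floating-point epsilon; clip the
    # resulting sub-zero distances without masking genuine negatives
    dist[(dist < 0) & (dist > -1e-9)] = 0.0
    np.fill_diagonal(dist, 0.0)
    return dist


def similarity_matrix(patterns: PatternMatrix, metric="pearson") -> np.ndarray:
    """Square symmetric similarity matrix (unit diagonal)."""
    dyads = pairwise_similarity(patterns, metric)
    n = patterns.n_participants
    idx = {p: k for k, p in enumerate(patterns.participant_ids)}
    mat = np.eye(n)
    for row in dyads.itertuples(index=False):
        i, j = idx[row.participant1], idx[row.participant2]
        mat[i, j] = mat[j, i] = row.similarity
    return mat


def similarity_to_reference(patterns: PatternMatrix, reference,
                            metric="pearson") -> pd.DataFrame:
    """Each participant's similarity to a single reference vector.

    ``metric='point_biserial'`` is the Pearson correlation between a
    participant's binary responses and a continuous reference (group
    average), computed after pairwise deletion of the participant's
    missing entries.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    if len(reference) != patterns.n_features:
        raise ValueError("reference length must equal n_features")
    if metric not in ("pearson", "cosine", "point_biserial"):
        raise ValueError("metric must be pearson, cosine or point_biserial")
    rows = []
    for pid, vec in zip(patterns.participant_ids, patterns.values):
        ok = ~np.isnan(vec)
        if metric == "cosine":
            s = _cosine(vec[ok], reference[ok])
        else:  # point-biserial is Pearson on the mixed binary/continuous pair
            s = _pearson(vec[ok], reference[ok])
        rows.append((pid, patterns.target_id, s, metric, np.isnan(s)))
    df = pd.DataFrame(rows, columns=["participant", "target",
                                     "similarity", "reference_method",
                                     "flag_undefined"])
    n_bad = int(df.flag_undefined.sum())
    if n_bad:
        logger.warning("%d undefined reference similarities flagged", n_bad)
    return df


def mean_pair_predictor(meta: pd.DataFrame, dyads: pd.DataFrame,
                        variable: str, out_col: str | None = None) -> pd.DataFrame:
    """Attach the pair-mean of a participant-level variable.

    The Anna Karenina predictor: for each dyad row the new column holds
    ``(x_i + x_j) / 2``.  ``meta`` must be indexed by participant id or
    contain a ``participant`` column.
    """
    out_col = out_col or f"mean_{variable}"
    lookup = _participant_lookup(meta, variable)
    x1 = dyads["participant1"].map(lookup)
    x2 = dyads["participant2"].map(lookup)
    if x1.isna().any() or x2.isna().any():
        raise ValueError(f"missing {variable!r} for some pair members")
    out = dyads.copy()
    out[out_col] = (x1.values + x2.values) / 2.0
    return out


def _participant_lookup(meta: pd.DataFrame, variable: str) -> pd.Series:
    if variable not in meta.columns:
        raise ValueError(f"variable {variable!r} not in participant table")
    if "participant" in meta.columns:
        return meta.set_index("participant")[variable]
    return meta[variable]


def build_dyad_covariates(meta: pd.DataFrame, dyads: pd.DataFrame,
                          match: list[str] = (),
                          abs_diff: list[str] = (),
                          euclidean: dict[str, list[str]] | None = None,
                          ) -> pd.DataFrame:
    """Pair-level covariates from participant-level metadata.

    ``match`` columns (categorical, e.g. gender/race) become 1.0 when the
    two members match and 0.0 otherwise.  ``abs_diff`` columns (continuous,
    e.g. age or word count) become the absolute within-pair difference;
    ``euclidean`` maps a new column name to a list of rating columns whose
    within-pair Euclidean distance is taken.  Every dissimilarity covariate
    is z-scored across pairs and then sign-flipped so that larger values
    mean more similar.
    """
    out = dyads.copy()
    for col in match:
        lookup = _participant_lookup(meta, col)
        a = out["participant1"].map(lookup)
        b = out["participant2"].map(lookup)
        if a.isna().any() or b.isna().any():
            raise ValueError(f"missing covariate {col!r} for a pair member")
        out[f"match_{col}"] = (a.values == b.values).astype(float)
    for col in abs_diff:
        lookup = _participant_lookup(meta, col)
        a = out["participant1"].map(lookup).astype(float)
        b = out["participant2"].map(lookup).astype(float)
        if a.isna().any() or b.isna().any():
            raise ValueError(f"missing covariate {col!r} for a pair member")
        out[f"sim_{col}"] = _flip_z((a - b).abs().values)
    for name, cols in (euclidean or {}).items():
        mat = meta.set_index("participant")[list(cols)] if "participant" in meta.columns \
            else meta[list(cols)]
        if mat.isna().any().any():
            raise ValueError(f"missing rating entries for {name!r}")
        a = mat.loc[out["participant1"]].values
        b = mat.loc[out["participant2"]].values
        out[f"sim_{name}"] = _flip_z(np.linalg.norm(a - b, axis=1))
    return out


def _flip_z(d: np.ndarray) -> np.ndarray:
    """z-score a dissimilarity across pairs, then flip sign to similarity."""
    sd = d.std(ddof=0)
    z = np.zeros_like(d, dtype=float) if sd == 0 else (d - d.mean()) / sd
    return -z
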