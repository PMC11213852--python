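"""Multiple correspondence analysis of the binary comorbidity matrix.

MCA here is correspondence analysis of the indicator matrix: each of the 22
diseases contributes two complementary 0/1 categories (present / absent),
giving an n × 44 indicator matrix Z.  With grand total N = n·Q (Q = 22
questions), P = Z/N is doubly centred by the row and column masses and
scaled, S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}; the SVD of S yields principal
inertias (squared singular values) and row principal coordinates
F = D_r^{-1/2} U Σ, which are the participant coordinates fed to
clustering.  The total inertia of a Q-question binary MCA is (J − Q)/Q with
J the number of non-degenerate categories.

Three dimension-retention rules are available; the retained dimensionality
is the single most influential free parameter of the pipeline and is
therefore logged explicitly.

* ``"scree"`` (default) — keep the leading dimensions up to the start of
  the *noise* plateau: the smallest k whose successive ratio λ_{k+1}/λ_k
  reaches 0.92 while λ_{k+1} already sits within a small multiple of the
  chance inertia 1/Q.  Raw MCA inertia shares are notoriously diluted
  across many near-chance dimensions, so cumulative-share thresholds drag
  half the noise floor into the embedding; plateau detection instead
  retains exactly the dimensions that stand out of it, including flat-
  topped structural spectra.
* an ``int`` — fixed dimensionality.
* a ``float`` in (0, 1] — smallest d with cumulative inertia share ≥ the
  threshold (optionally on Benzécri-corrected shares).

Never fewer than 2 dimensions are kept.  No Benzécri/Greenacre eigenvalue
correction is applied unless requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when the flag matrix carries no usable variation."""


@dataclass
class Embedding:
    coordinates: np.ndarray  # (n, kept_dims) row principal coordinates
    eigenvalues: np.ndarray  # all principal inertias, nonincreasing
    inertia_share: np.ndarray  # eigenvalues / total inertia
    kept_dims: int
    dropped_diseases: tuple = ()


DimRule = Union[int, float, str]

#: successive-eigenvalue ratio at which the spectrum counts as flat
SCREE_PLATEAU_RATIO = 0.92
#: multiple of the chance inertia 1/Q below which a flat stretch counts as noise
NOISE_CEILING_FACTOR = 1.25


def scree_dims(
    eigenvalues: np.ndarray,
    n_questions: int,
    plateau_ratio: float = SCREE_PLATEAU_RATIO,
    noise_ceiling_factor: float = NOISE_CEILING_FACTOR,
) -> int:
    """Number of leading dimensions before the *noise* plateau.

    Stops at the first k where the spectrum is flat (λ_{k+1}/λ_k ≥
    ``plateau_ratio``) *and* already inside the noise band (λ_{k+1} ≤
    ``noise_ceiling_factor``/Q, a small multiple of the chance inertia 1/Q).
    Requiring both conditions keeps near-equal *structural* eigenvalues —
    a flat top is not a noise plateau unless it sits at chance level.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    ceiling = noise_ceiling_factor / n_questions
    d = len(eigenvalues)
    for k in range(1, len(eigenvalues)):
        if (
            eigenvalues[k] / eigenvalues[k - 1] >= plateau_ratio
            and eigenvalues[k] <= ceiling
        ):
            d = k
            break
    return max(2, d)


def _benzecri(eigenvalues: np.ndarray, q: int) -> np.ndarray:
    thr = 1.0 / q
    adj = np.where(
        eigenvalues > thr, (q / (q - 1.0) * (eigenvalues - thr)) ** 2, 0.0
    )
    return adj


def mca_fit(
    flags,
    dim_rule: DimRule = "scree",
    *,
    benzecri: bool = False,
    column_names: Optional[Sequence[str]] = None,
) -> Embedding:
    """Fit MCA on an n × q boolean matrix and return row principal coordinates.

    ``dim_rule``: ``"scree"`` (default) stops at the eigenvalue plateau; an
    ``int`` keeps that many dimensions; a ``float`` in (0, 1] keeps the
    smallest d with cumulative inertia share ≥ the threshold.  At least 2
    dimensions are always kept.  Constant disease columns are dropped with a
    warning; an all-constant matrix raises :class:`DegenerateInputError`.
    """
    if isinstance(flags, pd.DataFrame):
        column_names = list(flags.columns)
        flags = flags.to_numpy()
    X = np.asarray(flags, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("need an n × q matrix with n >= 2")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("flag matrix must be binary")
    n, q_all = X.shape
    if column_names is None:
        column_names = [f"col_{j}" for j in range(q_all)]

    keep = ~((X == X[0]).all(axis=0))
    dropped = tuple(column_names[j] for j in np.flatnonzero(~keep))
    if dropped:
        logger.warning("dropping constant disease columns: %s", ", ".join(dropped))
    X = X[:, keep]
    q = X.shape[1]
    if q == 0:
        raise DegenerateInputError(
            "all disease columns are constant; MCA has zero total inertia"
        )

    # indicator matrix over 2q categories (present, absent per disease)
    Z = np.empty((n, 2 * q))
    Z[:, 0::2] = X
    Z[:, 1::2] = 1.0 - X
    N = Z.sum()
    P = Z / N
    r = P.sum(axis=1)  # = 1/n for every row
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)

    eigenvalues = sig**2
    # numerical floor: trailing near-zero inertias are structural zeros
    nontrivial = eigenvalues > 1e-12
    eigenvalues = eigenvalues[nontrivial]
    U = U[:, nontrivial]
    Vt = Vt[nontrivial]
    sig = sig[nontrivial]

    total_inertia = eigenvalues.sum()
    if total_inertia <= 1e-12:
        raise DegenerateInputError("zero total inertia after constant-column drop")
    share = eigenvalues / total_inertia

    rank_eigs = _benzecri(eigenvalues, q) if benzecri else eigenvalues
    rank_share = (
        rank_eigs / rank_eigs.sum() if rank_eigs.sum() > 0 else share
    )

    if isinstance(dim_rule, str):
        if dim_rule != "scree":
            raise ValueError(f"unrecognized dim_rule: {dim_rule!r}")
        d = scree_dims(eigenvalues, q)
    elif isinstance(dim_rule, (int, np.integer)) and not isinstance(dim_rule, bool):
        d = int(dim_rule)
    elif isinstance(dim_rule, float):
        if not 0 < dim_rule <= 1:
            raise ValueError("inertia threshold must be in (0, 1]")
        d = int(np.searchsorted(np.cumsum(rank_share), dim_rule - 1e-12) + 1)
    else:
        raise ValueError(f"unrecognized dim_rule: {dim_rule!r}")
    d = max(2, min(d, len(eigenvalues)))
    logger.info(
        "MCA: keeping %d of %d dimensions (cumulative inertia %.3f)",
        d,
        len(eigenvalues),
        float(np.cumsum(share)[d - 1]),
    )

    F = (U * sig) / np.sqrt(r)[:, None]  # row principal coordinates
    G = (Vt.T * sig) / np.sqrt(c)[:, None]  # column principal coordinates

    # sign convention: largest-magnitude category loading positive per dim
    for j in range(F.shape[1]):
        k = int(np.argmax(np.abs(G[:, j])))
        if G[k, j] < 0:
            F[:, j] = -F[:, j]
            G[:, j] = -G[:, j]

    return Embedding(
        coordinates=F[:, :d],
        eigenvalues=eigenvalues,
        inertia_share=share,
        kept_dims=d,
        dropped_diseases=dropped,
    )


def write_embedding(embedding: Embedding, person_ids, coords_path, eigen_path) -> None:
    """Write coordinates (person id + d columns) and the eigenvalue table."""
    d = embedding.kept_dims
    df = pd.DataFrame(
        embedding.coordinates, columns=[f"dim_{j + 1}" for j in range(d)]
    )
    df.insert(0, "person_id", list(person_ids))
    df.to_csv(coords_path, index=False)
    pd.DataFrame(
        {
            "dimension": np.arange(1, len(embedding.eigenvalues) + 1),
            "eigenvalue": embedding.eigenvalues,
            "inertia_share": embedding.inertia_share,
            "cumulative_share": np.cumsum(embedding.inertia_share),
        }
    ).to_csv(eigen_path, index=False)
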