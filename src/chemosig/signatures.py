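"""Mutational-signature extraction and constrained refitting.

Two complementary routes quantify mutational processes from a samples x
channels count matrix:

* de novo extraction (`KLNMF`): non-negative matrix factorisation under the
  generalised Kullback-Leibler divergence (the Poisson-flavoured objective
  standard for count catalogs), taking the best of many random restarts;
  `select_rank` picks the factorisation rank by requiring every de novo
  signature to resemble (cosine >= 0.8) a known reference signature.
* strict refitting (`StrictSignatureRefitter` / `refit_strict`):
  non-negative least squares of a sample's catalog on a constrained
  reference set, followed by greedy backward elimination of signatures
  whose removal barely changes the reconstruction cosine — suppressing the
  overfitting that plagues unconstrained refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF

# treatment-associated signatures are always retained for treated cohorts,
# whatever their de novo contribution
TREATMENT_SIGNATURES = {
    "SBS96": ("SBS17", "SBS35"),
    "DBS78": ("DBS5",),
    "ID83": ("ID8",),
}

# constrained refit sets: tissue-appropriate aging signatures plus the
# therapy signatures (platinum SBS35/DBS5, 5-FU SBS17 with 17a+17b merged,
# colibactin SBS88/ID18, radiation ID8)
CONSTRAINED_SETS = {
    "SBS96": ("SBS1", "SBS5", "SBS18", "SBS17", "SBS35", "SBS88"),
    "DBS78": ("DBS2", "DBS4", "DBS6", "DBS9", "DBS11", "DBS5"),
    "ID83": ("ID1", "ID2", "ID5", "ID8", "ID18"),
}


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative vectors (scale-free)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def normalise_columns(profiles: pd.DataFrame) -> pd.DataFrame:
    """Rescale each signature column to sum to 1."""
    sums = profiles.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("cannot normalise a zero signature column")
    return profiles / sums


def merge_signatures(reference: pd.DataFrame, group: list[str], new_name: str) -> pd.DataFrame:
    """Replace a group of signature columns by their renormalised sum.

    The merged column takes the position of the group's first member;
    exposures fitted on the merged profile then count the grouped
    processes' mutations jointly (used for SBS17a+SBS17b).
    """
    unknown = [g for g in group if g not in reference.columns]
    if unknown:
        raise ValueError(f"unknown signature name(s) {unknown}")
    merged = reference[group].sum(axis=1)
    merged = merged / merged.sum()
    out = reference.copy()
    first = list(out.columns).index(group[0])
    out = out.drop(columns=group)
    out.insert(first, new_name, merged)
    return out


@dataclass
class NMFResult:
    """Best-restart de novo factorisation of a count matrix."""

    rank: int
    signatures: pd.DataFrame  # channels x rank, columns sum to 1
    contributions: pd.DataFrame  # samples x rank, mutation counts
    objective: float
    n_restarts: int
    seed: int | None

    def reconstructed_cosines(self, X: pd.DataFrame) -> pd.Series:
        recon = self.contributions.to_numpy() @ self.signatures.to_numpy().T
        obs = X.to_numpy(dtype=float)
        out = [
            cosine_similarity(o, r) if o.sum() > 0 else np.nan
            for o, r in zip(obs, recon)
        ]
        return pd.Series(out, index=X.index)


class KLNMF:
    """Best-of-restarts NMF under generalised Kullback-Leibler divergence.

    Multiplicative-update NMF is run from ``n_restarts`` random
    non-negative initialisations; the factorisation with the lowest final
    divergence is kept.  Signatures (the H factor) are column-normalised to
    probability profiles with the contribution columns rescaled so the
    reconstruction is unchanged.

    Parameters
    ----------
    n_components : int
        Factorisation rank.
    n_restarts : int, default 100
        Random restarts.
    objective : {"kullback-leibler", "frobenius"}
        Beta divergence minimised.
    tol, max_iter : convergence tolerance and update cap per restart.
    random_state : int or None
        Master seed; restarts use seeds derived from it.

    Attributes (after ``fit``)
    --------------------------
    signatures_ : DataFrame, channels x rank
    contributions_ : DataFrame, samples x rank
    objective_ : float
    """

    def __init__(
        self,
        n_components: int,
        n_restarts: int = 100,
        objective: str = "kullback-leibler",
        tol: float = 1e-6,
        max_iter: int = 2000,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.objective = objective
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "n_restarts": self.n_restarts,
            "objective": self.objective,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "KLNMF":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "KLNMF":
        Xv = np.asarray(X, dtype=float)
        if (Xv < 0).any():
            raise ValueError("count matrix must be non-negative")
        if Xv.sum() == 0:
            raise ValueError("count matrix is all zero")
        if self.n_components >= min(Xv.shape):
            raise ValueError(
                f"rank {self.n_components} must be < min(n_samples, n_channels) = {min(Xv.shape)}"
            )
        seeds = np.random.SeedSequence(self.random_state).generate_state(self.n_restarts)
        best = None
        for s in seeds:
            model = NMF(
                n_components=self.n_components,
                init="random",
                solver="mu",
                beta_loss=self.objective,
                tol=self.tol,
                max_iter=self.max_iter,
                random_state=int(s),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W = model.fit_transform(Xv)
            if best is None or model.reconstruction_err_ < best[0]:
                best = (model.reconstruction_err_, W, model.components_)
        err, W, H = best
        # H: rank x channels -> profiles channels x rank, normalised
        scale = H.sum(axis=1)  # per-signature channel mass
        scale[scale == 0] = 1.0
        profiles = (H / scale[:, None]).T
        contrib = W * scale[None, :]
        names = [f"denovo_{i+1}" for i in range(self.n_components)]
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xv.shape[0])
        cols = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xv.shape[1])
        self.signatures_ = pd.DataFrame(profiles, index=cols, columns=names)
        self.contributions_ = pd.DataFrame(contrib, index=index, columns=names)
        self.objective_ = float(err)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).contributions_


def extract_denovo(
    matrix: pd.DataFrame,
    rank: int,
    n_restarts: int = 100,
    seed: int | None = None,
    objective: str = "kullback-leibler",
) -> NMFResult:
    """Functional form of `KLNMF`: de novo signatures from a count matrix."""
    est = KLNMF(
        n_components=rank, n_restarts=n_restarts, objective=objective, random_state=seed
    ).fit(matrix)
    return NMFResult(
        rank=rank,
        signatures=est.signatures_,
        contributions=est.contributions_,
        objective=est.objective_,
        n_restarts=n_restarts,
        seed=seed,
    )


def match_signatures(denovo: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Greedy 1:1 matching of de novo profiles to reference profiles.

    Repeatedly pairs the remaining (de novo, reference) columns with the
    highest cosine.  Returns one row per de novo signature with its match
    and score; unmatched de novo signatures (more de novo than reference)
    get a NaN match.
    """
    pairs = []
    remaining_d = list(denovo.columns)
    remaining_r = list(reference.columns)
    sims = {
        (d, r): cosine_similarity(denovo[d], reference[r])
        for d in remaining_d
        for r in remaining_r
    }
    while remaining_d and remaining_r:
        d, r = max(
            ((d, r) for d in remaining_d for r in remaining_r), key=lambda p: sims[p]
        )
        pairs.append({"denovo": d, "reference": r, "cosine": sims[(d, r)]})
        remaining_d.remove(d)
        remaining_r.remove(r)
    for d in remaining_d:
        pairs.append({"denovo": d, "reference": None, "cosine": np.nan})
    return pd.DataFrame(pairs)


def select_rank(
    matrix: pd.DataFrame,
    reference: pd.DataFrame,
    ranks,
    min_cosine: float = 0.8,
    n_restarts: int = 20,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the NMF rank whose de novo signatures all resemble references.

    For each candidate rank the de novo signatures are greedily matched to
    their closest reference; the chosen rank is the largest at which every
    de novo signature attains cosine >= ``min_cosine``.  Sub-threshold
    matches are flagged ``novel`` in the report rather than silently
    dropped — in treated cohorts these are candidate therapy signatures.
    If no rank qualifies, the rank with the best worst-case match wins,
    ties broken toward the smaller rank.
    """
    ranks = sorted(set(int(r) for r in ranks))
    if not ranks:
        raise ValueError("empty rank range")
    reports = []
    qualifying = []
    min_scores = {}
    for r in ranks:
        res = extract_denovo(matrix, r, n_restarts=n_restarts, seed=seed)
        rep = match_signatures(res.signatures, reference)
        rep.insert(0, "rank", r)
        rep["novel"] = ~(rep["cosine"] >= min_cosine)
        reports.append(rep)
        min_scores[r] = float(rep["cosine"].fillna(-1).min())
        if not rep["novel"].any():
            qualifying.append(r)
    report = pd.concat(reports, ignore_index=True)
    if qualifying:
        return max(qualifying), report
    best = max(ranks, key=lambda r: (min_scores[r], -r))
    return best, report


@dataclass
class ExposureVector:
    """Per-sample signature attribution in mutation counts."""

    sample_id: str
    mut_type: str
    exposures: pd.Series  # index: signature names (full allowed set; dropped = 0)
    reconstructed_cosine: float  # NaN for an all-zero catalog

    @property
    def total(self) -> float:
        return float(self.exposures.sum())


def _nnls_exposures(catalog: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    coef, _ = nnls(profiles, catalog)
    return coef


def refit_strict(
    catalog,
    allowed: pd.DataFrame,
    max_delta: float = 0.004,
    sample_id: str = "",
    mut_type: str = "",
) -> ExposureVector:
    """Strict constrained refit of one sample's channel counts.

    1. non-negative least squares of the catalog on the allowed profiles;
    2. greedy backward elimination: among remaining signatures, drop the
       one whose removal decreases the NNLS reconstruction cosine the
       least, as long as that decrease stays below ``max_delta``;
    3. final NNLS on the survivors; removed signatures get exposure 0.
    """
    cat = np.asarray(catalog, dtype=float)
    names = list(allowed.columns)
    P = allowed.to_numpy(dtype=float)
    if cat.shape[0] != P.shape[0]:
        raise ValueError("catalog length does not match signature channels")
    if (cat < 0).any():
        raise ValueError("catalog must be non-negative")
    if cat.sum() == 0:
        return ExposureVector(
            sample_id, mut_type, pd.Series(0.0, index=names), float("nan")
        )

    def recon_cos(idx: list[int]) -> float:
        coef = _nnls_exposures(cat, P[:, idx])
        recon = P[:, idx] @ coef
        if recon.sum() == 0:
            return 0.0
        return cosine_similarity(cat, recon)

    keep = list(range(len(names)))
    current = recon_cos(keep)
    while len(keep) > 1:
        candidates = []
        for j in keep:
            reduced = [i for i in keep if i != j]
            candidates.append((recon_cos(reduced), j))
        best_cos, drop = max(candidates, key=lambda t: (t[0], -t[1]))
        if current - best_cos < max_delta:
            keep = [i for i in keep if i != drop]
            current = best_cos
        else:
            break
    coef = _nnls_exposures(cat, P[:, keep])
    exposures = pd.Series(0.0, index=names)
    exposures.iloc[keep] = coef
    return ExposureVector(sample_id, mut_type, exposures, current)


class StrictSignatureRefitter:
    """Transformer applying the strict refit to every sample of a matrix.

    Parameters
    ----------
    signatures : DataFrame, channels x signatures
        Allowed (constrained) reference profiles, columns summing to 1.
    max_delta : float, default 0.004
        Largest tolerated per-step decrease in reconstruction cosine when
        eliminating a signature; 0 reduces the method to plain NNLS.

    ``transform`` maps a samples x channels count matrix to a samples x
    signatures exposure matrix (mutation counts).
    """

    def __init__(self, signatures: pd.DataFrame, max_delta: float = 0.004):
        self.signatures = signatures
        self.max_delta = max_delta

    def get_params(self, deep: bool = True) -> dict:
        return {"signatures": self.signatures, "max_delta": self.max_delta}

    def set_params(self, **params) -> "StrictSignatureRefitter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "StrictSignatureRefitter":
        sums = np.asarray(self.signatures.sum(axis=0), dtype=float)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1")
        self.n_signatures_ = self.signatures.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "n_signatures_"):
            self.fit()
        rows = {}
        self.reconstructed_cosines_ = {}
        for sid, row in X.iterrows():
            ev = refit_strict(row.to_numpy(), self.signatures, self.max_delta, sample_id=str(sid))
            rows[sid] = ev.exposures
            self.reconstructed_cosines_[sid] = ev.reconstructed_cosine
        out = pd.DataFrame(rows).T
        out.index.name = X.index.name
        return out[list(self.signatures.columns)]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit().transform(X)


def signature_set(
    mut_type: str,
    denovo_contributions: pd.Series | dict | None = None,
    treated: bool = True,
    min_contribution: float = 0.10,
) -> list[str]:
    """The constrained refit set for a mutation type.

    Starts from the configured tissue set (aging + therapy signatures) and
    keeps a signature only if its matched de novo relative contribution
    reaches ``min_contribution`` in at least one sample; therapy signatures
    are always retained for treated cohorts.  With no de novo information
    the full configured set is returned.
    """
    base = list(CONSTRAINED_SETS[mut_type])
    if denovo_contributions is None:
        return base
    contrib = pd.Series(denovo_contributions, dtype=float)
    always = set(TREATMENT_SIGNATURES[mut_type]) if treated else set()
    return [
        s for s in base if s in always or float(contrib.get(s, 0.0)) >= min_contribution
    ]


def relative_contributions(exposures: pd.DataFrame, burdens: pd.Series) -> pd.DataFrame:
    """Exposure counts divided by each sample's total burden of the type."""
    b = burdens.reindex(exposures.index)
    return exposures.div(b.replace(0, np.nan), axis=0)
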