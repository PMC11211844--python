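"""Likelihood of CRISPR-edited character matrices.

Each target site evolves independently along the lineage tree under an
irreversible continuous-time Markov chain with hidden states
``{0, 1..M, -1}``: the unedited state 0 acquires edit ``a`` at rate
``lambda * pi_a`` and is silenced (heritably missing, state -1) at rate
``nu``; an edited state keeps its edit but can still silence at rate
``nu``; the silent state is absorbing.  Observation adds per-leaf dropout:
an unsilenced state is seen as itself with probability ``1 - phi`` and as
"?" with probability ``phi``; the silent state is always seen as "?".

The progenitor (root) is unedited at every site.  Likelihoods marginalize
ancestral states by postorder pruning with per-node scaling; a brute-force
enumeration over ancestral realizations is provided as the testing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import trees
from ._flat import FlatTree, pmm_loglik_kernel
from .trees import MISSING, SILENT

__all__ = [
    "SiteAlphabet",
    "PMMParams",
    "CharacterMatrix",
    "transition_matrix",
    "dropout_emission",
    "site_loglik",
    "sequence_loglik",
    "brute_force_site_loglik",
]


@dataclass
class SiteAlphabet:
    """Alphabet of one target site: edits ``1..n_states`` plus 0 and -1.

    ``priors[a-1]`` is the probability that an edit, when it occurs, is
    edit ``a``; uniform by default.
    """

    n_states: int = 2
    priors: np.ndarray | None = None

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.priors is None:
            self.priors = np.full(self.n_states, 1.0 / self.n_states)
        else:
            self.priors = np.asarray(self.priors, dtype=float)
            if self.priors.shape != (self.n_states,):
                raise ValueError("priors must have length n_states")
            if abs(self.priors.sum() - 1.0) > 1e-9 or (self.priors < 0).any():
                raise ValueError("priors must be a probability vector")

    @property
    def hidden_states(self) -> list[int]:
        return [0, *range(1, self.n_states + 1), SILENT]


@dataclass
class PMMParams:
    """Sequence-model rates: edit rate lambda, silencing rate nu (both per
    unit time, >= 0) and dropout probability phi in [0, 1]."""

    lam: float
    nu: float = 0.0
    phi: float = 0.0

    def validate(self) -> None:
        if self.lam < 0 or self.nu < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")


@dataclass
class CharacterMatrix:
    """N cells x K sites of observed edit states.

    ``data`` is integer-coded: -2 missing ("?"), -1 silent, 0 unedited,
    1..M(k) edits.  ``alphabets[k]`` carries M(k) and the edit priors.
    """

    cells: list[str]
    data: np.ndarray
    alphabets: list[SiteAlphabet] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.cells):
            raise ValueError("data must be N x K with N == len(cells)")
        if not self.alphabets:
            self.alphabets = [
                SiteAlphabet(n_states=max(1, int(self.data[:, k].max(initial=1))))
                for k in range(self.data.shape[1])
            ]
        if len(self.alphabets) != self.data.shape[1]:
            raise ValueError("one alphabet per site required")
        for k, ab in enumerate(self.alphabets):
            col = self.data[:, k]
            if (col < MISSING).any() or (col > ab.n_states).any():
                raise ValueError(f"entry outside alphabet at site {k}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def reorder(self, cells: list[str]) -> "CharacterMatrix":
        idx = {c: i for i, c in enumerate(self.cells)}
        try:
            rows = [idx[c] for c in cells]
        except KeyError as e:
            raise KeyError(f"no sequence for cell {e.args[0]!r}") from None
        return CharacterMatrix(
            cells=list(cells), data=self.data[rows], alphabets=self.alphabets
        )

    def column(self, k: int) -> np.ndarray:
        return self.data[:, k]


# ---------------------------------------------------------------------------
# transition and emission probabilities
# ---------------------------------------------------------------------------

def generator(site: SiteAlphabet, params: PMMParams) -> np.ndarray:
    """Rate matrix over hidden states ordered ``[0, 1..M, -1]``."""
    params.validate()
    M = site.n_states
    Q = np.zeros((M + 2, M + 2))
    Q[0, 1:M + 1] = params.lam * site.priors
    Q[0, M + 1] = params.nu
    Q[0, 0] = -(params.lam + params.nu)
    for a in range(1, M + 1):
        Q[a, M + 1] = params.nu
        Q[a, a] = -params.nu
    return Q


def transition_matrix(
    site: SiteAlphabet, params: PMMParams, delta: float
) -> np.ndarray:
    """Transition probabilities over time ``delta``, hidden states ordered
    ``[0, 1..M, -1]``.

    Closed forms for the sparse irreversible generator:
    ``P(0->0) = exp(-(lam+nu) d)``,
    ``P(0->a) = pi_a exp(-nu d)(1 - exp(-lam d))``,
    ``P(0->-1) = 1 - exp(-nu d)``,
    ``P(a->a) = exp(-nu d)``, ``P(a->-1) = 1 - exp(-nu d)``,
    silent absorbing.  Edits never revert and never change identity.
    """
    params.validate()
    if delta < 0:
        raise ValueError("delta must be >= 0")
    M = site.n_states
    lam, nu = params.lam, params.nu
    e1 = np.exp(-(lam + nu) * delta)
    en = np.exp(-nu * delta)
    P = np.zeros((M + 2, M + 2))
    P[0, 0] = e1
    P[0, 1:M + 1] = site.priors * (en - e1)
    P[0, M + 1] = 1.0 - en
    for a in range(1, M + 1):
        P[a, a] = en
        P[a, M + 1] = 1.0 - en
    P[M + 1, M + 1] = 1.0
    return P


def dropout_emission(
    site: SiteAlphabet, phi: float, hidden: int, observed: int
) -> float:
    """Emission probability Phi(hidden, observed).

    ``hidden`` in ``{0, 1..M, -1}``; ``observed`` in ``{MISSING, 0, 1..M}``
    (the silent state can never be observed directly).
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must be in [0, 1]")
    M = site.n_states
    if hidden != SILENT and not 0 <= hidden <= M:
        raise ValueError(f"invalid hidden state {hidden}")
    if observed != MISSING and not 0 <= observed <= M:
        raise ValueError(f"invalid observed symbol {observed}")
    if hidden == SILENT:
        return 1.0 if observed == MISSING else 0.0
    if observed == MISSING:
        return phi
    return (1.0 - phi) if observed == hidden else 0.0


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _encode_column(column: np.ndarray, site: SiteAlphabet,
                   strict_silent: bool) -> np.ndarray:
    col = np.asarray(column, dtype=np.int64).copy()
    if ((col < MISSING) | (col > site.n_states)).any():
        raise ValueError("symbol outside the site alphabet")
    if (col == SILENT).any():
        if strict_silent:
            raise ValueError(
                "observed -1 (silent) entries are not directly observable; "
                "re-code as missing or call with strict_silent=False"
            )
        col[col == SILENT] = MISSING
    return col


def _loglik_flat(flat: FlatTree, obs: np.ndarray, pi: np.ndarray,
                 m_k: np.ndarray, params: PMMParams) -> tuple[float, np.ndarray]:
    delta = flat.branch_lengths()
    out_site = np.empty(obs.shape[1])
    total = pmm_loglik_kernel(
        flat.postorder, flat.child1, flat.child2, flat.is_leaf,
        flat.leaf_row, delta, obs, pi, m_k,
        params.lam, params.nu, params.phi, out_site,
    )
    return float(total), out_site


def _stack_sites(alphabets: list[SiteAlphabet]):
    m_k = np.array([ab.n_states for ab in alphabets], dtype=np.int64)
    mmax = int(m_k.max())
    pi = np.zeros((len(alphabets), mmax))
    for k, ab in enumerate(alphabets):
        pi[k, : ab.n_states] = ab.priors
    return pi, m_k


def site_loglik(
    tree: trees.LineageTree,
    column: np.ndarray,
    site: SiteAlphabet,
    params: PMMParams,
    strict_silent: bool = False,
) -> float:
    """Log marginal probability of one site's observed column.

    ``column`` follows ``tree.leaf_order()``.  Missing observations ("?")
    marginalize over hidden states through the dropout emission; a column
    that is impossible under the parameters (e.g. all-"?" with
    ``phi = nu = 0``) returns ``-inf`` rather than raising.
    """
    params.validate()
    flat = FlatTree(tree)
    if len(column) != len(flat.leaf_names):
        raise ValueError("column length must equal the number of leaves")
    obs = _encode_column(column, site, strict_silent).reshape(-1, 1)
    pi, m_k = _stack_sites([site])
    total, _ = _loglik_flat(flat, obs, pi, m_k, params)
    return total


def sequence_loglik(
    tree: trees.LineageTree,
    matrix: CharacterMatrix,
    params: PMMParams,
    strict_silent: bool = False,
) -> float:
    """Sum of per-site log-likelihoods (sites are independent)."""
    params.validate()
    flat = FlatTree(tree)
    mat = matrix.reorder(flat.leaf_names)
    obs = np.column_stack([
        _encode_column(mat.data[:, k], mat.alphabets[k], strict_silent)
        for k in range(mat.n_sites)
    ])
    pi, m_k = _stack_sites(mat.alphabets)
    total, _ = _loglik_flat(flat, obs, pi, m_k, params)
    return total


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_site_loglik(
    tree: trees.LineageTree,
    column: np.ndarray,
    site: SiteAlphabet,
    params: PMMParams,
    strict_silent: bool = False,
) -> float:
    """Exact likelihood by explicit summation over ancestral realizations.

    Enumerates every assignment of hidden states to the internal nodes
    (root fixed at 0); each leaf's hidden state is summed over its alphabet
    inside the product.  Intended as a testing oracle only; refuses trees
    with more than 7 internal nodes below the root.
    """
    import itertools

    params.validate()
    internal = [v for v in tree.preorder()
                if tree.children[v] and v != tree.root]
    if len(internal) > 7:
        raise ValueError("brute force limited to <= 7 internal nodes")
    leaves = tree.leaf_order()
    obs = _encode_column(column, site, strict_silent)
    obs_by_node = {v: obs[i] for i, v in enumerate(leaves)}
    states = site.hidden_states
    sidx = {s: i for i, s in enumerate(states)}
    Pcache = {
        v: transition_matrix(site, params, tree.branch_length[v])
        for v in tree.parent
    }
    total = 0.0
    for assign in itertools.product(states, repeat=len(internal)):
        x = {tree.root: 0}
        x.update(dict(zip(internal, assign)))
        p = 1.0
        for v in internal:
            p *= Pcache[v][sidx[x[tree.parent[v]]], sidx[x[v]]]
            if p == 0.0:
                break
        if p == 0.0:
            continue
        for i, w in enumerate(leaves):
            P = Pcache[w]
            pa = sidx[x[tree.parent[w]]]
            p *= sum(
                P[pa, sidx[h]]
                * dropout_emission(site, params.phi, h, obs_by_node[w])
                for h in states
            )
            if p == 0.0:
                break
        total += p
    return float(np.log(total)) if total > 0 else float("-inf")
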