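"""Flat array representation of a lineage tree and compiled likelihood kernels.

Both likelihoods are evaluated thousands of times inside the optimizer, so
the hot paths operate on plain integer/float arrays and are JIT-compiled
with numba.  The pure-Python semantics are identical (the ``njit`` wrapper
degrades to a no-op if numba is unavailable), and both kernels are checked
against independent oracles in the test suite: the spatial pruning against
the dense multivariate-normal likelihood, the sequence pruning against
exhaustive enumeration of ancestral states.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - numba is a declared dependency
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

_LOG2PI = float(np.log(2.0 * np.pi))


class FlatTree:
    """Array view of a :class:`~sdtrace.trees.LineageTree`.

    Node ids are re-used as array indices (parsing/simulation produce
    compact ids).  ``leaf_row[v]`` maps a leaf node to its row in
    lexicographic-by-name data order; ``bif_idx[v]`` maps a bifurcating
    internal node to its slot in the angle vector (preorder); ``sign[v]``
    is +1 for a first-listed child, -1 for a second, 0 under the root.
    ``free_idx[v]`` maps an internal non-root node to its slot in the
    unconstrained node-time vector (preorder).
    """

    def __init__(self, tree):
        n = tree.n_nodes
        ids = sorted(tree.children.keys())
        if ids != list(range(n)):
            raise ValueError("FlatTree requires compact node ids 0..n-1")
        self.tree = tree
        self.n = n
        self.root = tree.root
        self.parent = np.full(n, -1, dtype=np.int64)
        self.child1 = np.full(n, -1, dtype=np.int64)
        self.child2 = np.full(n, -1, dtype=np.int64)
        self.is_leaf = np.zeros(n, dtype=np.bool_)
        self.sign = np.zeros(n, dtype=np.float64)
        for v, p in tree.parent.items():
            self.parent[v] = p
        for v, ch in tree.children.items():
            if len(ch) >= 1:
                self.child1[v] = ch[0]
            if len(ch) == 2:
                self.child2[v] = ch[1]
                self.sign[ch[0]] = 1.0
                self.sign[ch[1]] = -1.0
            if not ch:
                self.is_leaf[v] = True
        self.preorder = np.array(tree.preorder(), dtype=np.int64)
        self.postorder = np.array(tree.postorder(), dtype=np.int64)

        leaves = tree.leaf_order()
        self.leaf_names = [tree.leaf_name[v] for v in leaves]
        self.leaf_row = np.full(n, -1, dtype=np.int64)
        for i, v in enumerate(leaves):
            self.leaf_row[v] = i

        self.bif_nodes = np.array(
            [v for v in self.preorder if tree.children[v]
             and len(tree.children[v]) == 2],
            dtype=np.int64,
        )
        self.bif_idx = np.full(n, -1, dtype=np.int64)
        for i, v in enumerate(self.bif_nodes):
            self.bif_idx[v] = i
        self.n_bif = len(self.bif_nodes)
        self.bif_c1 = self.child1[self.bif_nodes]
        self.bif_c2 = self.child2[self.bif_nodes]

        self.free_nodes = np.array(
            [v for v in self.preorder
             if v != self.root and not self.is_leaf[v]],
            dtype=np.int64,
        )
        self.free_idx = np.full(n, -1, dtype=np.int64)
        for i, v in enumerate(self.free_nodes):
            self.free_idx[v] = i
        self.n_free = len(self.free_nodes)

    def branch_lengths(self) -> np.ndarray:
        delta = np.zeros(self.n)
        for v, bl in self.tree.branch_length.items():
            if bl is None:
                raise ValueError("branch lengths are unset")
            delta[v] = bl
        return delta

    def displacement_shifts(self, r: float, theta: np.ndarray):
        """Per-edge deterministic displacement (dx, dy) given angles.

        ``theta[i]`` is the division angle of ``bif_nodes[i]``; the edge to
        a first-listed child is shifted by +r(cos, sin), the second by the
        negative.  Edges under the unifurcating root get no displacement.
        """
        dx = np.zeros(self.n)
        dy = np.zeros(self.n)
        if r == 0.0 or self.n_bif == 0:
            return dx, dy
        cos = r * np.cos(theta)
        sin = r * np.sin(theta)
        dx[self.bif_c1] = cos
        dy[self.bif_c1] = sin
        dx[self.bif_c2] = -cos
        dy[self.bif_c2] = -sin
        return dx, dy


# ---------------------------------------------------------------------------
# node-time reparameterization
# ---------------------------------------------------------------------------

@njit(cache=True)
def times_from_raw(preorder, parent, is_leaf, free_idx, raw, tau):
    """Map an unconstrained vector to node times (root 0, leaves tau).

    Each internal non-root node sits at
    ``t_parent + (tau - t_parent) * sigmoid(raw)``, evaluated root-down, so
    the common-sampling-time constraint holds exactly by construction.
    """
    n = preorder.shape[0]
    t = np.zeros(n)
    for i in range(n):
        v = preorder[i]
        p = parent[v]
        if p < 0:
            t[v] = 0.0
        elif is_leaf[v]:
            t[v] = tau
        else:
            s = 1.0 / (1.0 + np.exp(-raw[free_idx[v]]))
            t[v] = t[p] + (tau - t[p]) * s
    return t


@njit(cache=True)
def deltas_from_times(parent, t):
    n = parent.shape[0]
    delta = np.zeros(n)
    for v in range(n):
        if parent[v] >= 0:
            delta[v] = t[v] - t[parent[v]]
    return delta


# ---------------------------------------------------------------------------
# spatial likelihood: linear-time Gaussian pruning
# ---------------------------------------------------------------------------

@njit(cache=True)
def sd_prune_kernel(postorder, parent, child1, child2, is_leaf, leaf_row,
                    delta, dx, dy, xs, ys, sig2, floor, rho2):
    """Symmetric-displacement Gaussian pruning, root factor left open.

    Returns ``(ll_contrasts, mx_root, my_root, V_root)``: the accumulated
    contrast log-likelihood plus the root message — the GLS estimate of
    the root position per axis and its variance.  The full likelihood
    given a root position adds ``logN(x0; mx_root, V_root)`` per axis; the
    restricted (REML) likelihood — equivalently the likelihood with the
    root position integrated under a flat prior — is ``ll_contrasts``
    alone.

    Each node carries the conditional distribution of its subtree's leaf
    coordinates given its own position, summarized as (mean, extra
    variance); combining two children contributes one Gaussian "contrast"
    factor per axis, and the root (known position x0, y0) contributes the
    final factor.  O(n) per call; x and y share all variances.

    Two displacement treatments share this kernel.  Conditional on known
    division angles, ``dx``/``dy`` carry the per-edge deterministic shifts
    and ``rho2 = 0``.  With angles marginalized, ``rho2 = r^2/2`` is the
    per-axis variance of the latent Gaussian division displacement (the
    second-moment match of a uniformly oriented displacement of length r):
    each daughter then gains ``rho2`` extra variance and the two daughters
    are anti-correlated (covariance ``-rho2``), which modifies the contrast
    variance and the weighted-mean combination below.
    """
    n = postorder.shape[0]
    mx = np.zeros(n)
    my = np.zeros(n)
    V = np.zeros(n)
    ll = 0.0
    for i in range(n):
        u = postorder[i]
        if is_leaf[u]:
            row = leaf_row[u]
            mx[u] = xs[row]
            my[u] = ys[row]
            V[u] = 0.0
        else:
            a = child1[u]
            da = delta[a] if delta[a] > floor else floor
            max_ = mx[a] - dx[a]
            may_ = my[a] - dy[a]
            Va = V[a] + sig2 * da
            if child2[u] >= 0:
                b = child2[u]
                db = delta[b] if delta[b] > floor else floor
                mbx = mx[b] - dx[b]
                mby = my[b] - dy[b]
                Vb = V[b] + sig2 * db
                # bivariate combine with sibling covariance -rho2:
                # A = Va + rho2, B = Vb + rho2, C = -rho2
                A = Va + rho2
                B = Vb + rho2
                Vs = A + B + 2.0 * rho2     # contrast variance A + B - 2C
                ll += -_LOG2PI - np.log(Vs) \
                    - 0.5 * ((max_ - mbx) ** 2 + (may_ - mby) ** 2) / Vs
                wa = B + rho2               # B - C
                wb = A + rho2               # A - C
                mx[u] = (wa * max_ + wb * mbx) / Vs
                my[u] = (wa * may_ + wb * mby) / Vs
                V[u] = (A * B - rho2 * rho2) / Vs
            else:
                mx[u] = max_
                my[u] = may_
                V[u] = Va
    root = postorder[n - 1]
    return ll, mx[root], my[root], V[root]


@njit(cache=True)
def sd_loglik_kernel(postorder, parent, child1, child2, is_leaf, leaf_row,
                     delta, dx, dy, xs, ys, x0, y0, sig2, floor, rho2):
    """Full spatial log-likelihood for a known root position."""
    ll, mxr, myr, Vr = sd_prune_kernel(
        postorder, parent, child1, child2, is_leaf, leaf_row,
        delta, dx, dy, xs, ys, sig2, floor, rho2)
    ll += -_LOG2PI - np.log(Vr) \
        - 0.5 * ((x0 - mxr) ** 2 + (y0 - myr) ** 2) / Vr
    return ll


# ---------------------------------------------------------------------------
# sequence likelihood: pruning over the irreversible editing chain
# ---------------------------------------------------------------------------

@njit(cache=True)
def pmm_loglik_kernel(postorder, child1, child2, is_leaf, leaf_row,
                      delta, obs, pi, m_k, lam, nu, phi, out_site):
    """Pruning likelihood of a character matrix under the editing chain.

    Hidden states are indexed 0 (unedited), 1..Mmax (edits), S-1 (silent).
    ``obs`` holds leaf observations with -2 for missing ("?"); ``pi[k, a-1]``
    is the prior of edit ``a`` at site ``k`` (zero-padded past ``m_k[k]``).
    Per-site log-likelihoods are written to ``out_site``; the sum is
    returned.  A site with probability zero yields -inf, not an error.
    """
    n = postorder.shape[0]
    K = obs.shape[1]
    S = pi.shape[1] + 2
    F = np.zeros((n, K, S))
    logscale = np.zeros(K)
    for i in range(n):
        u = postorder[i]
        if is_leaf[u]:
            row = leaf_row[u]
            for k in range(K):
                code = obs[row, k]
                if code == -2:
                    for a in range(m_k[k] + 1):
                        F[u, k, a] = phi
                    F[u, k, S - 1] = 1.0
                else:
                    F[u, k, code] = 1.0 - phi
        else:
            for k in range(K):
                for s in range(S):
                    F[u, k, s] = 1.0
            for ci in range(2):
                c = child1[u] if ci == 0 else child2[u]
                if c < 0:
                    continue
                d = delta[c]
                e1 = np.exp(-(lam + nu) * d)
                en = np.exp(-nu * d)
                for k in range(K):
                    fs = F[c, k, S - 1]
                    sa = 0.0
                    for a in range(1, S - 1):
                        sa += pi[k, a - 1] * F[c, k, a]
                    g0 = e1 * F[c, k, 0] + (en - e1) * sa + (1.0 - en) * fs
                    F[u, k, 0] *= g0
                    for a in range(1, S - 1):
                        F[u, k, a] *= en * F[c, k, a] + (1.0 - en) * fs
                    F[u, k, S - 1] *= fs
            for k in range(K):
                m = F[u, k, 0]
                for s in range(1, S):
                    if F[u, k, s] > m:
                        m = F[u, k, s]
                if m > 0.0:
                    for s in range(S):
                        F[u, k, s] /= m
                    logscale[k] += np.log(m)
    root = postorder[n - 1]
    total = 0.0
    for k in range(K):
        p0 = F[root, k, 0]
        if p0 > 0.0:
            out_site[k] = np.log(p0) + logscale[k]
        else:
            out_site[k] = -np.inf
        total += out_site[k]
    return total
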