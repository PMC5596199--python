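"""De novo motif discovery: ZOOPS EM, motif E-values, and motif comparison.

The site model is ZOOPS (zero or one occurrence per sequence, either strand):
each sequence carries a motif site with probability gamma, uniformly placed
over its windows on both strands, against a 0-order background.  The model is
fit by EM from seeded k-mer starts; the observed-data log-likelihood is
tracked and is guaranteed non-decreasing.

Motif significance is a QFAST-style combined p-value: each reported site's
scan p-value is first corrected for the per-sequence search (Sidak over the
number of windows in that sequence), the corrected p-values are combined with
the product-of-p formula ``P = p * sum_{k<n} (-ln p)^k / k!``, and the result
is scaled by the number of (width, start) configurations searched.  This is a
deliberately simple, exactly testable surrogate for MEME's E-value; it lives
on the same reporting scale (planted motifs in this package reach far below
the conventional 1e-15 reporting threshold, shuffled input does not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from ._util import decode, encode
from .motifs import PWM, estimate_background

E_VALUE_REPORTING_THRESHOLD = 1e-15


@dataclass
class DiscoveredMotif:
    """A motif found by ZOOPS EM: matrix, supporting sites and significance."""

    pwm: PWM
    sites: list[tuple[str, int, str]]  # (sequence id, 0-based offset, strand)
    e_value: float
    log10_e_value: float
    consensus: str
    ll_trace: list[float] = field(default_factory=list)


@dataclass
class MotifMatch:
    """Best alignment of a query motif against a target motif."""

    query: str
    target: str
    offset: int
    orientation: str  # '+' or '-'
    similarity: float  # mean column Pearson r over aligned columns
    p_value: float
    significant: bool


class _SequenceSet:
    """Encoded sequences with per-width window bookkeeping (both strands)."""

    def __init__(self, sequences: Mapping[str, str]):
        self.ids = list(sequences)
        self.codes = [encode(sequences[i]) for i in self.ids]
        self.rc_codes = [(3 - c)[::-1].copy() for c in self.codes]  # non-ACGT -> -1 sentinel
        for arr, rc in zip(self.codes, self.rc_codes):
            rc[(3 - arr)[::-1] < 0] = 4
        self.lengths = np.array([len(c) for c in self.codes])
        self.background = estimate_background(sequences.values())

    def windows(self, w: int, masked: list[np.ndarray] | None = None):
        """Stack all valid windows of width w on both strands.

        Returns (win, seq_idx, pos, strand_code) where pos is the 0-based
        forward-strand offset of the window start and strand_code is 0/1.
        """
        wins, seq_idx, pos, strand = [], [], [], []
        for i, codes in enumerate(self.codes):
            L = len(codes)
            n = L - w + 1
            if n <= 0:
                continue
            for sc, arr in ((0, codes), (1, self.rc_codes[i])):
                view = np.lib.stride_tricks.sliding_window_view(arr, w)
                valid = (view < 4).all(axis=1)
                if masked is not None:
                    mvalid = ~np.lib.stride_tricks.sliding_window_view(
                        masked[i], w).any(axis=1)
                    if sc == 1:
                        mvalid = mvalid[::-1]
                    valid &= mvalid
                idx = np.nonzero(valid)[0]
                if idx.size == 0:
                    continue
                wins.append(view[idx])
                seq_idx.append(np.full(idx.size, i))
                p = idx if sc == 0 else (L - w - idx)
                pos.append(p)
                strand.append(np.full(idx.size, sc))
        if not wins:
            return (np.empty((0, w), dtype=np.int8), np.empty(0, int),
                    np.empty(0, int), np.empty(0, int))
        order_key = np.concatenate(seq_idx)
        order = np.argsort(order_key, kind="stable")
        return (np.concatenate(wins)[order], order_key[order],
                np.concatenate(pos)[order], np.concatenate(strand)[order])


def _zoops_em(win, seq_idx, n_seqs, bg, w, init_pwm, pseudocount=0.25,
              max_iter=200, tol=1e-4):
    """Run ZOOPS EM from one start.  Returns (probs, gamma, ll_trace, Z)."""
    n_win = win.shape[0]
    logbg = np.log(bg)
    bg_ll = logbg[win].sum(axis=1)  # background log-lik of each window's content
    counts_per_seq = np.bincount(seq_idx, minlength=n_seqs).astype(float)
    m_i = np.maximum(counts_per_seq, 1.0)
    probs = init_pwm.copy()
    gamma = 0.5
    ll_trace: list[float] = []
    cols = np.arange(w)
    for _ in range(max_iter):
        logp = np.log(probs)
        site_ll = logp[cols, win].sum(axis=1)
        # per-window log weight of "site here" relative to all-background
        lw = np.log(gamma) - np.log(m_i[seq_idx]) + site_ll - bg_ll
        # per-sequence logsumexp over windows, plus the no-site term log(1-gamma)
        seq_max = np.full(n_seqs, -np.inf)
        np.maximum.at(seq_max, seq_idx, lw)
        no_site = math.log(max(1 - gamma, 1e-300))
        seq_max = np.maximum(seq_max, no_site)
        expsum = np.bincount(seq_idx, weights=np.exp(lw - seq_max[seq_idx]),
                             minlength=n_seqs)
        expsum += np.exp(no_site - seq_max)
        seq_log_norm = seq_max + np.log(expsum)
        # MAP objective: observed-data ll plus the Dirichlet pseudocount prior;
        # this is the quantity EM with pseudocounts drives monotonically upward
        prior = float((pseudocount * bg * 4 * np.log(probs)).sum())
        ll = float(seq_log_norm.sum()) + prior
        if ll_trace and ll < ll_trace[-1] - 1e-6:
            raise AssertionError("ZOOPS EM objective decreased")
        ll_trace.append(ll)
        z = np.exp(lw - seq_log_norm[seq_idx])  # posterior site probabilities
        # M-step
        site_mass = np.bincount(seq_idx, weights=z, minlength=n_seqs)
        has_windows = counts_per_seq > 0
        gamma = float(np.clip(site_mass[has_windows].mean(), 1e-4, 1 - 1e-4))
        new_counts = np.stack([np.bincount(win[:, j], weights=z, minlength=4)
                               for j in range(w)])
        new_probs = new_counts + pseudocount * bg * 4
        new_probs /= new_probs.sum(axis=1, keepdims=True)
        delta = np.abs(new_probs - probs).max()
        probs = new_probs
        if delta < tol:
            break
    return probs, gamma, ll_trace, z


def _init_from_window(window: np.ndarray, match_prob: float = 0.6) -> np.ndarray:
    w = window.shape[0]
    probs = np.full((w, 4), (1 - match_prob) / 3)
    probs[np.arange(w), window] = match_prob
    return probs


def discover_zoops(sequences: Mapping[str, str], width_range: tuple[int, int] = (8, 18),
                   n_motifs: int = 3, restarts: int = 20, seed: int | None = None,
                   pseudocount: float = 0.25, max_iter: int = 200,
                   tol: float = 1e-4) -> list[DiscoveredMotif]:
    """ZOOPS EM motif discovery over a range of widths with site masking.

    For each width, ``restarts`` seeded k-mer starts are screened with a short
    EM burn-in; the highest-likelihood starts are run to convergence.  The
    best motif across widths (smallest E-value) is reported, its sites are
    masked, and the search repeats up to ``n_motifs`` times.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    data = _SequenceSet(sequences)
    w_lo, w_hi = width_range
    if all(l < w_lo for l in data.lengths):
        raise ValueError("all sequences shorter than the minimum motif width")
    rng = np.random.default_rng(seed)
    masked = [np.zeros(len(c), dtype=bool) for c in data.codes]
    n_seqs = len(data.ids)
    total_windows = int(sum(2 * max(0, l - w + 1) for l in data.lengths
                            for w in range(w_lo, w_hi + 1)))
    n_widths = w_hi - w_lo + 1
    found: list[DiscoveredMotif] = []
    for _ in range(n_motifs):
        best: DiscoveredMotif | None = None
        for w in range(w_lo, w_hi + 1):
            win, seq_idx, pos, strand = data.windows(w, masked)
            if win.shape[0] < 2:
                continue
            # screen seeded starts with a short burn-in, refine the best
            n_cand = min(restarts, win.shape[0])
            cand = rng.choice(win.shape[0], size=n_cand, replace=False)
            screened = []
            for c in cand:
                init = _init_from_window(win[c])
                try:
                    probs, gamma, ll, _ = _zoops_em(
                        win, seq_idx, n_seqs, data.background, w, init,
                        pseudocount, max_iter=8, tol=tol)
                except AssertionError:
                    continue
                screened.append((ll[-1], c))
            screened.sort(key=lambda t: (-t[0], t[1]))
            best_w = None
            for _, c in screened[:2]:
                init = _init_from_window(win[c])
                probs, gamma, ll, z = _zoops_em(
                    win, seq_idx, n_seqs, data.background, w, init,
                    pseudocount, max_iter=max_iter, tol=tol)
                if best_w is None or ll[-1] > best_w[2][-1]:
                    best_w = (probs, gamma, ll, z)
            if best_w is None:
                continue
            probs, gamma, ll, z = best_w
            pwm = PWM(probs, data.background)
            sites = _extract_sites(data, z, seq_idx, pos, strand, w)
            if not sites:
                continue
            e, log10_e = _evalue_from_sites(pwm, data, sites,
                                            n_configs=total_windows)
            motif = DiscoveredMotif(pwm=pwm, sites=sites, e_value=e,
                                    log10_e_value=log10_e,
                                    consensus=pwm.consensus(), ll_trace=ll)
            if best is None or motif.log10_e_value < best.log10_e_value:
                best = motif
        if best is None:
            break
        found.append(best)
        for sid, off, _strand in best.sites:
            i = data.ids.index(sid)
            masked[i][off:off + best.pwm.width] = True
    return found


def _extract_sites(data, z, seq_idx, pos, strand, w):
    """Best window per sequence where the posterior site mass reaches 0.5."""
    n_seqs = len(data.ids)
    best_z = np.zeros(n_seqs)
    np.maximum.at(best_z, seq_idx, z)
    best_j = np.full(n_seqs, -1)
    for j in np.nonzero(z == best_z[seq_idx])[0][::-1]:
        best_j[seq_idx[j]] = j  # ties resolved to the first occurrence
    site_mass = np.bincount(seq_idx, weights=z, minlength=n_seqs)
    sites = []
    for s in range(n_seqs):
        if site_mass[s] >= 0.5 and best_j[s] >= 0:
            j = best_j[s]
            sites.append((data.ids[s], int(pos[j]), "+-"[int(strand[j])]))
    return sites


def _site_kmer(data: _SequenceSet, sid: str, off: int, strand: str, w: int) -> str:
    i = data.ids.index(sid)
    codes = data.codes[i][off:off + w]
    if strand == "-":
        codes = (3 - codes)[::-1]
    return decode(codes)


def qfast_combine(p_values: Sequence[float]) -> float:
    """QFAST product-of-p combination: P = p * sum_{k=0}^{n-1} (-ln p)^k / k!."""
    return math.exp(qfast_combine_log(p_values))


def qfast_combine_log(p_values: Sequence[float]) -> float:
    """Natural log of the QFAST combined p-value (stable for tiny inputs)."""
    p = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    n = len(p)
    ln_prod = float(np.log(p).sum())
    if n == 1 or ln_prod == 0.0:
        return min(ln_prod, 0.0)
    t = -ln_prod
    ks = np.arange(n)
    ln_terms = ks * math.log(t) - gammaln(ks + 1)
    return min(ln_prod + float(logsumexp(ln_terms)), 0.0)


def motif_evalue(motif: DiscoveredMotif, sequences: Mapping[str, str],
                 n_configs: int | None = None) -> float:
    """Recompute the E-value of a discovered motif against its sequence set."""
    data = _SequenceSet(sequences)
    if n_configs is None:
        n_configs = int(sum(2 * max(0, l - motif.pwm.width + 1)
                            for l in data.lengths))
    e, _ = _evalue_from_sites(motif.pwm, data, motif.sites, n_configs)
    return e


def _evalue_from_sites(pwm: PWM, data: _SequenceSet,
                       sites: Sequence[tuple[str, int, str]],
                       n_configs: int) -> tuple[float, float]:
    w = pwm.width
    site_ps = []
    for sid, off, strand in sites:
        i = data.ids.index(sid)
        kmer_p = pwm.score_pvalue(pwm.score(_site_kmer(data, sid, off, strand, w)))
        m = 2 * max(1, data.lengths[i] - w + 1)  # windows searched in this sequence
        # Sidak correction for taking the best window of the sequence
        if kmer_p * m < 1e-8:
            corrected = kmer_p * m
        else:
            corrected = -math.expm1(m * math.log1p(-min(kmer_p, 1 - 1e-12)))
        site_ps.append(min(max(corrected, 1e-300), 1.0))
    ln_p = qfast_combine_log(site_ps)
    ln_e = ln_p + math.log(max(n_configs, 1))
    log10_e = ln_e / math.log(10)
    return max(math.exp(max(ln_e, -700)), 5e-324), log10_e


# -- motif-motif comparison -------------------------------------------------

def _column_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two probability columns.

    Degenerate columns need a convention: two (near-)identical columns agree
    perfectly (r=1) even when constant, while a constant column carries no
    signal against a non-constant one (r=0).
    """
    if np.abs(a - b).max() < 1e-9:
        return 1.0
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _best_alignment(q: np.ndarray, t: np.ndarray, min_overlap: int):
    """Best (similarity, offset) over all shifts with enough aligned columns."""
    wq, wt = q.shape[0], t.shape[0]
    best = (-np.inf, 0)
    for offset in range(-(wq - min_overlap), wt - min_overlap + 1):
        qs, ts = max(0, -offset), max(0, offset)
        n = min(wq - qs, wt - ts)
        if n < min_overlap:
            continue
        rs = [_column_r(q[qs + k], t[ts + k]) for k in range(n)]
        sim = float(np.mean(rs))
        if sim > best[0]:
            best = (sim, offset)
    return best


def compare_motifs(query: PWM, targets: Mapping[str, PWM], min_overlap: int = 4,
                   permutations: int = 1000, seed: int | None = None,
                   p_threshold: float = 0.001,
                   query_name: str = "query") -> list[MotifMatch]:
    """Align a query motif against target motifs by column correlation.

    Similarity is the mean Pearson r of aligned probability columns over the
    best offset, testing both query orientations.  The p-value is a
    conditional permutation test: target columns are shuffled (seeded) and
    the similarity is recomputed at the observed offset and orientation.
    Conditioning on the alignment keeps the null honest for short motifs
    whose column multiset is degenerate — re-optimizing the offset for every
    permutation lets minimal 4-column overlaps of duplicated letter columns
    match by chance and washes out true full-length matches.
    """
    rng = np.random.default_rng(seed)
    out = []
    for name, target in targets.items():
        t = target.probs
        stats = []
        for orient, qm in (("+", query), ("-", query.reverse_complement())):
            sim, offset = _best_alignment(qm.probs, t, min_overlap)
            stats.append((sim, offset, orient))
        sim, offset, orient = max(stats, key=lambda s: s[0])
        if not np.isfinite(sim):
            continue
        qprobs = (query if orient == "+" else query.reverse_complement()).probs
        qs, ts = max(0, -offset), max(0, offset)
        n_aligned = min(qprobs.shape[0] - qs, t.shape[0] - ts)
        worse = 0
        for _ in range(permutations):
            perm = t[rng.permutation(t.shape[0])]
            rs = [_column_r(qprobs[qs + k], perm[ts + k])
                  for k in range(n_aligned)]
            if float(np.mean(rs)) >= sim - 1e-12:
                worse += 1
        p = (1 + worse) / (permutations + 1)
        out.append(MotifMatch(query=query_name, target=name, offset=offset,
                              orientation=orient, similarity=sim, p_value=p,
                              significant=p <= p_threshold))
    out.sort(key=lambda m: m.p_value)
    return out
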