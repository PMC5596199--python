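"""Position weight matrices: scoring, exact null p-values, and genome scanning.

A :class:`PWM` is a ``width x 4`` matrix of per-position base probabilities
over A,C,G,T with a 0-order background.  Windows are scored as log-odds in
bits, ``sum_j log2(p_j(base)/bg(base))``, and significance comes from the
exact distribution of that score under the background model, computed by
dynamic programming on a discretized score lattice (the classical
Staden/FIMO construction).

Coordinates follow GFF conventions: hits are 1-based inclusive on the forward
strand regardless of which strand matched.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ALPHABET, decode, encode, revcomp

HIT_COLUMNS = ["replicon", "start", "end", "strand", "score", "p_value"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifHit:
    """One scored occurrence of a motif on a replicon."""

    replicon: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float


class PWM:
    """Probability matrix over ACGT with a 0-order background.

    Parameters
    ----------
    probs
        Array of shape (width, 4); every row must sum to 1.
    background
        Length-4 base frequencies; uniform by default.
    """

    def __init__(self, probs, background=None):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if (probs <= 0).any():
            raise ValueError("PWM entries must be strictly positive (apply a pseudocount)")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9) or (bg <= 0).any():
            raise ValueError("background must be 4 positive frequencies summing to 1")
        self.probs = probs
        self.background = bg
        self._dist_cache: dict[float, tuple[np.ndarray, np.ndarray, int]] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sites(cls, sites: Sequence[str], pseudocount: float = 0.25,
                   background=None) -> "PWM":
        """Column frequencies of equal-length ACGT sites plus an additive pseudocount."""
        if not sites:
            raise ValueError("empty site list")
        w = len(sites[0])
        if any(len(s) != w for s in sites):
            raise ValueError("ragged site list")
        counts = np.zeros((w, 4))
        for s in sites:
            codes = encode(s)
            if (codes >= 4).any():
                raise ValueError(f"non-ACGT base in site {s!r}")
            counts[np.arange(w), codes] += 1
        probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
        return cls(probs, background)

    @classmethod
    def from_consensus(cls, consensus: str, fixed: float = 0.97,
                       background=None) -> "PWM":
        """PWM from an IUPAC consensus: listed bases share ``fixed`` probability."""
        rows = []
        for letter in consensus.upper():
            allowed = IUPAC.get(letter)
            if allowed is None:
                raise ValueError(f"unknown IUPAC letter {letter!r}")
            row = np.full(4, (1 - fixed) / (4 - len(allowed)) if len(allowed) < 4 else 0.25)
            for b in allowed:
                row[ALPHABET.index(b)] = fixed / len(allowed)
            rows.append(row / row.sum())
        return cls(np.array(rows), background)

    # -- basic properties --------------------------------------------------

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/bg) in bits, shape (width, 4)."""
        return np.log2(self.probs / self.background)

    def information_content(self) -> float:
        return float((self.probs * np.log2(self.probs / self.background)).sum())

    def consensus(self, fixed_threshold: float = 0.8) -> str:
        """IUPAC-free consensus: the base where max column probability >= threshold, else N."""
        out = []
        for row in self.probs:
            i = int(np.argmax(row))
            out.append(ALPHABET[i] if row[i] >= fixed_threshold else "N")
        return "".join(out)

    def reverse_complement(self) -> "PWM":
        """Column order reversed, base order complemented; an involution."""
        return PWM(self.probs[::-1, ::-1], self.background[::-1])

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one site column-wise from the matrix."""
        codes = [rng.choice(4, p=row) for row in self.probs]
        return decode(np.array(codes))

    # -- scoring -----------------------------------------------------------

    def score(self, kmer: str) -> float:
        """Log-odds score in bits; NaN if the k-mer contains a non-ACGT base."""
        if len(kmer) != self.width:
            raise ValueError(f"k-mer length {len(kmer)} != width {self.width}")
        codes = encode(kmer)
        if (codes >= 4).any():
            return float("nan")
        return float(self.log_odds[np.arange(self.width), codes].sum())

    def window_scores(self, codes: np.ndarray) -> np.ndarray:
        """Scores of every window of an encoded sequence; -inf where a window
        contains a non-ACGT base."""
        n = len(codes) - self.width + 1
        if n <= 0:
            return np.empty(0)
        lo = np.hstack([self.log_odds, np.full((self.width, 1), -np.inf)])
        out = np.zeros(n)
        for j in range(self.width):
            out += lo[j, codes[j:j + n]]
        return out

    # -- exact null distribution -------------------------------------------

    def _distribution(self, granularity: float):
        """Lattice pmf of the score under the background: (pmf, tail, offset).

        ``pmf[i]`` is the probability that the lattice-rounded score equals
        ``(offset + i) * granularity``; ``tail`` is the suffix cumulative sum.
        """
        if granularity in self._dist_cache:
            return self._dist_cache[granularity]
        ints = np.round(self.log_odds / granularity).astype(np.int64)
        offset = int(ints.min(axis=1).sum())
        span = int((ints.max(axis=1) - ints.min(axis=1)).sum()) + 1
        pmf = np.zeros(span)
        pmf[0] = 1.0
        mins = ints.min(axis=1)
        for j in range(self.width):
            shifts = ints[j] - mins[j]
            new = np.zeros(span)
            for b in range(4):
                s = int(shifts[b])
                seg = pmf[: span - s] if s else pmf
                new[s:s + len(seg)] += self.background[b] * seg[:span - s]
            pmf = new
        tail = np.cumsum(pmf[::-1])[::-1]
        self._dist_cache[granularity] = (pmf, tail, offset)
        return pmf, tail, offset

    def score_pvalue(self, score: float, granularity: float = 1e-4) -> float:
        """P(score' >= score) for a background-drawn k-mer, exact up to the
        score lattice.  A slack of ``width`` lattice steps guarantees that a
        k-mer achieving exactly ``score`` is always counted."""
        _, tail, offset = self._distribution(granularity)
        idx = int(round(score / granularity)) - self.width - offset
        if idx <= 0:
            return 1.0
        if idx >= len(tail):
            return 5e-324  # above the maximum achievable score
        p = float(tail[idx])
        return p if p > 0 else 5e-324

    def score_pvalues(self, scores: np.ndarray, granularity: float = 1e-4) -> np.ndarray:
        """Vectorized :meth:`score_pvalue`; -inf scores get p-value 1 (skipped later)."""
        _, tail, offset = self._distribution(granularity)
        scores = np.asarray(scores, dtype=float)
        out = np.ones_like(scores)
        finite = np.isfinite(scores)
        raw = np.round(scores[finite] / granularity).astype(np.int64) - self.width - offset
        idx = np.clip(raw, 0, len(tail) - 1)
        vals = tail[idx]
        vals[raw <= 0] = 1.0
        out[finite] = np.maximum(vals, 5e-324)
        return out

    def pvalue_score_threshold(self, p_threshold: float, granularity: float = 1e-4) -> float:
        """Smallest score whose p-value is <= ``p_threshold`` (+inf if none)."""
        _, tail, offset = self._distribution(granularity)
        ok = np.nonzero(tail <= p_threshold)[0]
        if ok.size == 0:
            return float("inf")
        return (ok[0] + offset + self.width) * granularity

    # -- MEME minimal format -----------------------------------------------

    def to_meme_block(self, name: str, nsites: int | None = None,
                      e_value: float | None = None) -> str:
        head = f"MOTIF {name}\nletter-probability matrix: alength= 4 w= {self.width}"
        if nsites is not None:
            head += f" nsites= {nsites}"
        if e_value is not None:
            head += f" E= {e_value:.3e}"
        rows = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in self.probs)
        return head + "\n" + rows + "\n"


def estimate_background(sequences: Iterable[str], both_strands: bool = True) -> np.ndarray:
    """0-order base frequencies of a sequence set (strand-symmetrized by default)."""
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if both_strands:
        counts = counts + counts[::-1]
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts = counts + 1.0  # pseudocount keeps all frequencies positive
    return counts / counts.sum()


# -- scanning ---------------------------------------------------------------

def scan(pwm: PWM, sequences: Mapping[str, str], p_threshold: float = 1e-4,
         both_strands: bool = True, granularity: float = 1e-4) -> pd.DataFrame:
    """All windows with null p-value <= threshold, as a hit table.

    Minus-strand matches are found by scanning the reverse-complement matrix
    along the forward strand, so coordinates are always forward-strand
    1-based inclusive.
    """
    records = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    for strand, mat in strands:
        thresh = mat.pvalue_score_threshold(p_threshold, granularity)
        for name, seq in sequences.items():
            codes = encode(seq)
            scores = mat.window_scores(codes)
            sel = np.nonzero(scores >= thresh)[0]
            if sel.size == 0:
                continue
            pvals = mat.score_pvalues(scores[sel], granularity)
            for i, sc, pv in zip(sel, scores[sel], pvals):
                records.append((name, int(i) + 1, int(i) + pwm.width, strand,
                                float(sc), float(pv)))
    df = pd.DataFrame(records, columns=HIT_COLUMNS)
    return df.sort_values(["replicon", "start", "strand"]).reset_index(drop=True)


# -- upstream windows -------------------------------------------------------

def extract_upstream(annotation, sequences: Mapping[str, str],
                     window: int = 200) -> tuple[dict[str, str], set[str]]:
    """Strand-aware 5' windows for every gene.

    Returns (gene_id -> upstream sequence in promoter orientation, ids whose
    window was truncated at a replicon end).  Windows are not truncated at
    neighbouring ORFs.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out: dict[str, str] = {}
    truncated: set[str] = set()
    for row in annotation.genes.itertuples(index=False):
        seq = sequences[row.replicon]
        if row.strand == "+":
            lo = max(0, row.start - 1 - window)
            sub = seq[lo:row.start - 1]
            if row.start - 1 - window < 0:
                truncated.add(row.gene_id)
        else:
            hi = min(len(seq), row.end + window)
            sub = revcomp(seq[row.end:hi])
            if row.end + window > len(seq):
                truncated.add(row.gene_id)
        out[row.gene_id] = sub
    return out, truncated


# -- MEME / BED I/O ---------------------------------------------------------

def write_meme(motifs: Mapping[str, PWM], path: str | os.PathLike,
               background: np.ndarray | None = None,
               nsites: Mapping[str, int] | None = None,
               e_values: Mapping[str, float] | None = None) -> None:
    """Minimal MEME motif format writer."""
    first = next(iter(motifs.values()), None)
    bg = background if background is not None else (
        first.background if first is not None else np.full(4, 0.25))
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for name, pwm in motifs.items():
            fh.write(pwm.to_meme_block(
                name,
                nsites=None if nsites is None else nsites.get(name),
                e_value=None if e_values is None else e_values.get(name)) + "\n")


def read_meme(path: str | os.PathLike) -> dict[str, PWM]:
    """Read a minimal MEME motif file (MOTIF + letter-probability matrix blocks)."""
    with open(path) as fh:
        text = fh.read()
    bg = np.full(4, 0.25)
    m = re.search(r"Background letter frequencies[^\n]*\n([^\n]+)", text)
    if m:
        toks = m.group(1).split()
        freq = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks) - 1, 2)}
        if set("ACGT") <= set(freq):
            bg = np.array([freq[b] for b in ALPHABET])
            bg = bg / bg.sum()
    motifs: dict[str, PWM] = {}
    blocks = re.split(r"^MOTIF\s+", text, flags=re.M)[1:]
    for block in blocks:
        lines = block.strip().splitlines()
        name = lines[0].split()[0]
        mat_idx = next(i for i, l in enumerate(lines)
                       if l.lstrip().startswith("letter-probability matrix"))
        wm = re.search(r"w=\s*(\d+)", lines[mat_idx])
        width = int(wm.group(1))
        rows = []
        for line in lines[mat_idx + 1: mat_idx + 1 + width]:
            rows.append([float(x) for x in line.split()[:4]])
        probs = np.array(rows)
        probs = probs / probs.sum(axis=1, keepdims=True)
        probs = np.clip(probs, 1e-9, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
        motifs[name] = PWM(probs, bg)
    return motifs


def hits_to_bed(hits: pd.DataFrame, path: str | os.PathLike,
                name: str = "motif") -> None:
    """Write hits as BED6 (0-based half-open start, as the format requires)."""
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            fh.write(f"{row.replicon}\t{row.start - 1}\t{row.end}\t{name}"
                     f"\t{row.score:.4f}\t{row.strand}\n")


def bed_to_hits(path: str | os.PathLike) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, _name, score, strand = line.split()[:6]
            records.append((chrom, int(start) + 1, int(end), strand,
                            float(score), float("nan")))
    return pd.DataFrame(records, columns=HIT_COLUMNS)


def consensus_match_count(query: str, reference: str) -> int:
    """Best count of reference positions matched by a query consensus.

    Maximized over all offsets and both query orientations.  A reference
    position counts as matched when it is N, or when the aligned query letter
    equals it; reference positions left uncovered match only if they are N.
    """
    best = 0
    for q in (query.upper(), revcomp(query.upper())):
        for offset in range(-len(q) + 1, len(reference)):
            n = 0
            for i, ref in enumerate(reference.upper()):
                if ref == "N":
                    n += 1
                    continue
                j = i - offset
                if 0 <= j < len(q) and q[j] == ref:
                    n += 1
            best = max(best, n)
    return best


def fixk_reference_pwm(fixed: float = 0.97) -> PWM:
    """Reference PWM for the palindromic FixK/Fnr-family binding consensus
    TTGAT-N4-ATCAA, with informative positions at the given probability."""
    return PWM.from_consensus("TTGATNNNNATCAA", fixed=fixed)
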