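"""Synonymous/nonsynonymous substitution accounting and tests of selection.

Counting follows the Nei-Gojobori (1986) scheme: potential synonymous and
nonsynonymous sites per codon, observed differences averaged with equal
weight over minimal mutational pathways (stop-traversing pathways
excluded), Jukes-Cantor correction of the proportions, and a global dN/dS
as the ratio of mean pairwise dN to mean pairwise dS.  A codon-column
bootstrap supplies the z-test of neutrality, and a parsimony flavour of
SLAC (ancestral codons from Fitch parsimony, per-edge tallies, binomial
site test) classifies individual codons as invariant, neutral, or under
positive/negative selection at the p < 0.1 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from . import _codon
from ._codon import SENSE_CODONS, pathway_counts, potential_sites
from .phylo import AncestralAssignment
from .seqcore import CodingSequence, CodonAlignment


def ng86_potential_sites(codon: str) -> tuple[float, float]:
    """Potential synonymous and nonsynonymous sites ``(s, n)`` of a sense
    codon; ``s + n = 3`` (changes to stop codons count as nonsynonymous)."""
    return potential_sites(codon)


def jukes_cantor(p: float) -> float:
    """JC69-corrected distance; NaN when the proportion saturates (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


class PairwiseDnDs(NamedTuple):
    dN: float
    dS: float
    Nd: float
    Sd: float
    N: float
    S: float

    @property
    def ratio(self) -> float | None:
        """dN/dS, or None when dS is zero or undefined."""
        if not np.isfinite(self.dS) or self.dS == 0:
            return None
        return self.dN / self.dS


def _encode(seq: CodingSequence) -> np.ndarray:
    return _codon.encode_codons(seq.nucleotides)


def pairwise_dn_ds(a: CodingSequence, b: CodingSequence) -> PairwiseDnDs:
    """NG86 pairwise dN and dS with Jukes-Cantor correction.

    Observed synonymous/nonsynonymous differences are pathway-averaged per
    codon; potential sites are the average of the two sequences'.  A
    saturated proportion (p >= 3/4) yields NaN for that rate.
    """
    if len(a.nucleotides) != len(b.nucleotides):
        raise ValueError("sequences must have equal length")
    SD, ND, SP, NP = _codon.tables()
    ia, ib = _encode(a), _encode(b)
    Sd = float(SD[ia, ib].sum())
    Nd = float(ND[ia, ib].sum())
    S = float((SP[ia].sum() + SP[ib].sum()) / 2.0)
    N = float((NP[ia].sum() + NP[ib].sum()) / 2.0)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return PairwiseDnDs(dN=jukes_cantor(pN), dS=jukes_cantor(pS),
                        Nd=Nd, Sd=Sd, N=N, S=S)


@dataclass
class GlobalDnDs:
    ratio: float | None  # None when undefined (no synonymous signal)
    mean_dN: float
    mean_dS: float
    n_pairs: int  # pairs with defined (unsaturated) dN and dS


def global_dnds(aln: CodonAlignment) -> GlobalDnDs:
    """Global dN/dS: mean pairwise dN over mean pairwise dS.

    Pairs with saturated (undefined) rates are dropped; an alignment of
    identical sequences has no synonymous signal and the ratio is None.
    """
    if len(aln) < 2:
        raise ValueError("global dN/dS needs >=2 members")
    SD, ND, SP, NP = _codon.tables()
    enc = np.vstack([_encode(m) for m in aln.members])
    s_tot = SP[enc].sum(axis=1)
    n_tot = NP[enc].sum(axis=1)
    dns, dss = [], []
    for i in range(len(aln)):
        for j in range(i + 1, len(aln)):
            Sd = SD[enc[i], enc[j]].sum()
            Nd = ND[enc[i], enc[j]].sum()
            S = (s_tot[i] + s_tot[j]) / 2.0
            N = (n_tot[i] + n_tot[j]) / 2.0
            dn = jukes_cantor(Nd / N if N > 0 else 0.0)
            ds = jukes_cantor(Sd / S if S > 0 else 0.0)
            if np.isfinite(dn) and np.isfinite(ds):
                dns.append(dn)
                dss.append(ds)
    if not dns:
        return GlobalDnDs(ratio=None, mean_dN=float("nan"),
                          mean_dS=float("nan"), n_pairs=0)
    mean_dn = float(np.mean(dns))
    mean_ds = float(np.mean(dss))
    ratio = mean_dn / mean_ds if mean_ds > 0 else None
    return GlobalDnDs(ratio=ratio, mean_dN=mean_dn, mean_dS=mean_ds,
                      n_pairs=len(dns))


class ZTestResult(NamedTuple):
    z: float
    p: float
    n_bootstrap: int


def codon_z_test(
    aln: CodonAlignment, n_bootstrap: int = 1000, seed: int = 0
) -> ZTestResult:
    """Codon-bootstrap z-test of neutrality (negative-selection alternative).

    Z = (mean dS - mean dN) / SE, where the means are over sequence pairs
    and SE is the standard deviation of (mean dS - mean dN) over codon-
    column bootstrap resamples.  One-tailed p: large positive Z (an excess
    of synonymous change) is evidence of purifying selection.  Returns NaN
    for degenerate alignments with no substitution signal.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    if len(aln) < 2:
        raise ValueError("z-test needs >=2 members")
    SD, ND, SP, NP = _codon.tables()
    enc = np.vstack([_encode(m) for m in aln.members])
    n_seq, n_col = enc.shape
    pair_idx = [(i, j) for i in range(n_seq) for j in range(i + 1, n_seq)]
    P = len(pair_idx)
    sdm = np.empty((P, n_col), dtype=np.float32)
    ndm = np.empty((P, n_col), dtype=np.float32)
    spm = np.empty((P, n_col), dtype=np.float32)
    npm = np.empty((P, n_col), dtype=np.float32)
    for k, (i, j) in enumerate(pair_idx):
        sdm[k] = SD[enc[i], enc[j]]
        ndm[k] = ND[enc[i], enc[j]]
        spm[k] = (SP[enc[i]] + SP[enc[j]]) / 2.0
        npm[k] = (NP[enc[i]] + NP[enc[j]]) / 2.0

    def _delta(w: np.ndarray) -> np.ndarray:
        """Mean (dS - dN) over pairs for column-weight matrix w (cols x B)."""
        Sd = sdm @ w
        Nd = ndm @ w
        S = spm @ w
        N = npm @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            ps = np.where(S > 0, Sd / S, 0.0)
            pn = np.where(N > 0, Nd / N, 0.0)
            ds = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * ps / 3.0), np.nan)
            dn = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * pn / 3.0), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(ds - dn, axis=0)

    obs = float(_delta(np.ones((n_col, 1)))[0])
    if not np.isfinite(obs) or (sdm.sum() + ndm.sum()) == 0:
        warnings.warn("degenerate alignment: z-test undefined")
        return ZTestResult(float("nan"), float("nan"), n_bootstrap)
    rng = np.random.default_rng(seed)
    W = rng.multinomial(n_col, np.full(n_col, 1.0 / n_col),
                        size=n_bootstrap).T.astype(np.float32)
    deltas = _delta(W)
    se = float(np.nanstd(deltas, ddof=1))
    if se == 0 or not np.isfinite(se):
        warnings.warn("zero bootstrap variance: z-test undefined")
        return ZTestResult(float("nan"), float("nan"), n_bootstrap)
    z = obs / se
    p = float(stats.norm.sf(z))
    return ZTestResult(z, p, n_bootstrap)


@dataclass
class CodonCounts:
    """Per-codon-column observed and potential substitution counts."""

    nd: np.ndarray  # observed nonsynonymous changes per column
    sd: np.ndarray  # observed synonymous changes per column
    n_pot: np.ndarray  # nonsynonymous potential sites (averaged over members)
    s_pot: np.ndarray  # synonymous potential sites

    @property
    def codon_count(self) -> int:
        return self.nd.size


@dataclass
class SiteSelectionCall:
    codon_index: int  # 1-based
    nd: float
    sd: float
    n_pot: float
    s_pot: float
    dn_minus_ds: float
    p_value: float
    klass: str  # positive | negative | neutral | invariant


def count_invariant_codons(aln: CodonAlignment) -> int:
    """Number of codon columns with a single codon state across members."""
    enc = np.vstack([_encode(m) for m in aln.members])
    return int((enc == enc[0]).all(axis=0).sum())


def codon_counts_from_scan(calls: Sequence[SiteSelectionCall]) -> CodonCounts:
    return CodonCounts(
        nd=np.array([c.nd for c in calls]),
        sd=np.array([c.sd for c in calls]),
        n_pot=np.array([c.n_pot for c in calls]),
        s_pot=np.array([c.s_pot for c in calls]),
    )


def codon_counts_from_consensus(aln: CodonAlignment) -> CodonCounts:
    """Fallback counting frame: pathway-averaged differences of every member
    against the majority-rule consensus codon per column."""
    SD, ND, SP, NP = _codon.tables()
    enc = np.vstack([_encode(m) for m in aln.members])
    n_col = enc.shape[1]
    nd = np.zeros(n_col)
    sd = np.zeros(n_col)
    consensus = np.empty(n_col, dtype=np.int16)
    for c in range(n_col):
        vals, counts = np.unique(enc[:, c], return_counts=True)
        consensus[c] = vals[np.argmax(counts)]  # ties: lowest codon index
    for c in range(n_col):
        sd[c] = SD[enc[:, c], consensus[c]].sum()
        nd[c] = ND[enc[:, c], consensus[c]].sum()
    return CodonCounts(nd=nd, sd=sd, n_pot=NP[enc].mean(axis=0),
                       s_pot=SP[enc].mean(axis=0))


def site_selection_scan(
    tree,
    aln: CodonAlignment,
    anc: AncestralAssignment,
    alpha: float = 0.1,
) -> list[SiteSelectionCall]:
    """Per-codon selection classification from parsimony ancestral states.

    For each codon column, substitutions are tallied over every tree edge
    (pathway-averaged when an edge spans a multi-step codon change); the
    observed nonsynonymous count is tested against the neutral expectation
    n_c / (n_c + s_c) with a two-tailed binomial test.  Columns with no
    changes are invariant; otherwise p < ``alpha`` with dN > dS (per-site
    rates) is positive selection and with dN < dS negative selection.
    """
    SD, ND, SP, NP = _codon.tables()
    enc = np.vstack([_encode(m) for m in aln.members])
    edges = [
        node for node in tree.preorder_node_iter() if node.parent_node is not None
    ]
    calls: list[SiteSelectionCall] = []
    for col in range(1, aln.codon_count + 1):
        assigned = anc.column(col)
        nd_c = sd_c = 0.0
        for node in edges:
            s_parent = assigned[node.parent_node]
            s_child = assigned[node]
            if s_parent != s_child:
                s_step, n_step = pathway_counts(s_parent, s_child)
                sd_c += s_step
                nd_c += n_step
        n_pot = float(NP[enc[:, col - 1]].mean())
        s_pot = float(SP[enc[:, col - 1]].mean())
        total = nd_c + sd_c
        if total == 0:
            calls.append(
                SiteSelectionCall(col, 0.0, 0.0, n_pot, s_pot, 0.0, 1.0,
                                  "invariant")
            )
            continue
        dn = nd_c / n_pot if n_pot > 0 else 0.0
        ds = sd_c / s_pot if s_pot > 0 else 0.0
        q = n_pot / (n_pot + s_pot)
        k = int(round(nd_c))
        n = max(int(round(total)), k)
        p = float(stats.binomtest(k, n, q).pvalue) if n > 0 else 1.0
        if p < alpha and dn > ds:
            klass = "positive"
        elif p < alpha and dn < ds:
            klass = "negative"
        else:
            klass = "neutral"
        calls.append(
            SiteSelectionCall(col, nd_c, sd_c, n_pot, s_pot, dn - ds, p, klass)
        )
    return calls
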