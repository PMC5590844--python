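"""Haplotype-copying ("chromosome painting") engine.

A recipient haplotype is modelled as an imperfect mosaic of a panel of donor
haplotypes (the classic Li–Stephens copying model with a uniform prior over
donors).  Between adjacent sites separated by ``g`` cM the copied donor is
retained with probability ``exp(-switch_rate * g / 100)``; on a switch the
new donor is uniform over the panel (so a switch may land on the same
donor).  The observed allele differs from the copied donor's allele with
probability ``emission_mismatch`` per site.

The module computes, per recipient: posterior copying probabilities
(forward-backward with per-site rescaling), expected copied centimorgans and
expected segment counts per donor group, maximum-likelihood parameter
estimates via E-M, and posterior path samples used downstream to build
coancestry curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core_io import GroupAssignment, HaplotypeAlignment

logger = logging.getLogger(__name__)


@dataclass
class CopyingParams:
    """Fitted switch and emission parameters of the copying model."""

    switch_rate: float          # expected switch intensity per Morgan
    emission_mismatch: float    # per-site copying error probability

    def __post_init__(self) -> None:
        if not self.switch_rate > 0:
            raise ValueError("switch_rate must be positive")
        if not 0 <= self.emission_mismatch < 0.5:
            raise ValueError("emission_mismatch must lie in [0, 0.5)")


@dataclass
class PaintingSummary:
    """Expected copied length and segment count per donor group for one recipient."""

    recipient: str
    donor_groups: list
    copied_cM: pd.Series                 # genome-wide expected cM per donor group
    expected_segments: pd.Series         # genome-wide expected segment count per group
    per_chrom_cM: pd.DataFrame           # chrom x donor group expected cM
    chrom_sites: pd.Series               # number of sites per chromosome

    @property
    def profile(self) -> pd.Series:
        """Genome-wide painting profile f_k (copied-length shares, sums to 1)."""
        total = float(self.copied_cM.sum())
        if total <= 0:
            raise ValueError("no copied length; cannot normalize profile")
        return self.copied_cM / total

    @property
    def per_chrom_profile(self) -> pd.DataFrame:
        totals = self.per_chrom_cM.sum(axis=1)
        return self.per_chrom_cM.div(totals, axis=0)


@dataclass
class PaintingPathSample:
    """Donor-group labels sampled from the copying posterior.

    ``labels[chrom]`` has shape (n_recipient_haplotypes, n_samples, n_sites)
    holding integer codes into ``groups``.
    """

    groups: list
    recipients: list
    n_samples: int
    labels: dict = field(default_factory=dict)     # chrom -> int16 array
    cM: dict = field(default_factory=dict)         # chrom -> site cM positions


# ---------------------------------------------------------------------------
# Donor bookkeeping
# ---------------------------------------------------------------------------

def _hap_rows(aln: HaplotypeAlignment, ident: str) -> list[int]:
    """Rows of ``ident``: a haplotype id, or both haplotypes of a sample id."""
    if ident in aln.haplotype_ids:
        return [aln.haplotype_ids.index(ident)]
    rows = [i for i, h in enumerate(aln.haplotype_ids)
            if h == f"{ident}_A" or h == f"{ident}_B"]
    if not rows:
        raise ValueError(f"unknown recipient or donor id {ident!r}")
    return rows


def _donor_panel(aln: HaplotypeAlignment, donors: GroupAssignment,
                 exclude_rows: set[int], leave_one_out: bool,
                 recipient_group=None):
    """Resolve donor rows and their group codes, applying leave-one-out.

    Under leave-one-out the recipient's own haplotypes are removed, so its
    group contributes n_k - 1 individuals; a donor group left empty after
    exclusion is a hard error.
    """
    rows, codes = [], []
    groups = donors.groups
    for k, g in enumerate(groups):
        g_rows: list[int] = []
        for ident in donors.members(g):
            g_rows.extend(_hap_rows(aln, ident))
        if leave_one_out or g == recipient_group:
            g_rows = [r for r in g_rows if r not in exclude_rows]
        if not g_rows:
            if g == recipient_group:
                # a singleton recipient group simply vanishes from the donors
                logger.info("recipient's own group %r has n_k = 1; dropped "
                            "from the donor set", g)
                continue
            raise ValueError(f"donor group {g!r} has no members after exclusions")
        rows.extend(g_rows)
        codes.extend([k] * len(g_rows))
    kept = sorted(set(codes))
    remap = {old: new for new, old in enumerate(kept)}
    codes = [remap[c] for c in codes]
    groups = [groups[k] for k in kept]
    return np.asarray(rows), np.asarray(codes), groups


def _site_weights(cM: np.ndarray) -> np.ndarray:
    """Half-interval cM weight per site; weights sum to the chromosome span."""
    if len(cM) == 1:
        return np.zeros(1)
    w = np.empty_like(cM)
    w[0] = (cM[1] - cM[0]) / 2
    w[-1] = (cM[-1] - cM[-2]) / 2
    if len(cM) > 2:
        w[1:-1] = (cM[2:] - cM[:-2]) / 2
    return w


# ---------------------------------------------------------------------------
# Forward-backward core
# ---------------------------------------------------------------------------

class _ChromPosteriors:
    """Holds per-chromosome forward-backward output for a batch of recipients."""

    __slots__ = ("gamma_sum_by_group", "copied_cM", "first_site_group",
                 "switch_to_group", "switch_prob", "mismatch_exp", "loglik",
                 "alphas", "stay", "n_sites")

    def __init__(self):
        pass


def _forward_backward(donor_H: np.ndarray, obs: np.ndarray, cM: np.ndarray,
                      params: CopyingParams, group_codes: np.ndarray,
                      n_groups: int, keep_alphas: bool = False) -> _ChromPosteriors:
    """Scaled forward-backward over one chromosome for R recipients jointly.

    donor_H: (D, S) donor alleles; obs: (R, S) recipient alleles.
    Returns group-aggregated posterior summaries; optionally retains the
    scaled forward messages for posterior path sampling.
    """
    D, S = donor_H.shape
    R = obs.shape[0]
    e = params.emission_mismatch
    # emission of 0 would make mismatching paths impossible; floor for stability
    e = max(e, 1e-12)
    gaps = np.diff(cM)
    stay = np.exp(-params.switch_rate * gaps / 100.0)

    out = _ChromPosteriors()
    out.stay = stay
    out.n_sites = S

    def emis(t: int) -> np.ndarray:
        match = obs[:, t][:, None] == donor_H[None, :, t]
        return np.where(match, 1.0 - e, e)

    alphas = np.empty((S, R, D))
    loglik = np.zeros(R)
    a = emis(0) / D
    c = a.sum(axis=1, keepdims=True)
    a /= c
    loglik += np.log(c[:, 0])
    alphas[0] = a
    for t in range(1, S):
        s = stay[t - 1]
        pred = s * a + (1.0 - s) / D
        a = pred * emis(t)
        c = a.sum(axis=1, keepdims=True)
        a /= c
        loglik += np.log(c[:, 0])
        alphas[t] = a
    out.loglik = loglik
    out.alphas = alphas if keep_alphas else None

    # backward pass, accumulating group-aggregated statistics on the fly
    w = _site_weights(cM)
    onehot = np.zeros((D, n_groups))
    onehot[np.arange(D), group_codes] = 1.0

    copied = np.zeros((R, n_groups))
    switch_to = np.zeros((R, n_groups))
    switch_prob = np.zeros((R, S - 1)) if S > 1 else np.zeros((R, 0))
    mismatch = np.zeros(R)

    beta = np.ones((R, D))
    gamma = alphas[S - 1] * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    copied += w[S - 1] * (gamma @ onehot)
    mismatch += (gamma * (obs[:, S - 1][:, None] != donor_H[None, :, S - 1])).sum(axis=1)
    for t in range(S - 2, -1, -1):
        s = stay[t]
        v = emis(t + 1) * beta                       # (R, D)
        ct = (alphas[t] * (s * v + (1.0 - s) / D * v.sum(axis=1, keepdims=True))).sum(
            axis=1, keepdims=True)
        # expected switch events at this gap (E-M statistic) and, for segment
        # counting, only those landing on a *different* donor haplotype —
        # a switch back onto the current haplotype opens no new segment
        land = (1.0 - s) / D * v / ct                # (R, D) all switch landings
        new_chunk = land * (1.0 - alphas[t])         # different-haplotype landings
        switch_to += new_chunk @ onehot
        switch_prob[:, t] = land.sum(axis=1)
        beta = (s * v + (1.0 - s) / D * v.sum(axis=1, keepdims=True)) / ct
        gamma = alphas[t] * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        copied += w[t] * (gamma @ onehot)
        mismatch += (gamma * (obs[:, t][:, None] != donor_H[None, :, t])).sum(axis=1)

    # segment attribution: the first site opens a segment in its group, every
    # switch (to any donor haplotype) opens a new one in the landing group
    out.copied_cM = copied
    out.first_site_group = gamma @ onehot            # gamma at t=0 after loop
    out.switch_to_group = switch_to
    out.switch_prob = switch_prob
    out.mismatch_exp = mismatch
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _paint_batch(aln: HaplotypeAlignment, donors: GroupAssignment,
                 recipient, params: CopyingParams, leave_one_out: bool,
                 keep_alphas: bool = False):
    cM = aln.require_cM()
    if isinstance(recipient, (list, tuple)):
        # joint batch over several recipients sharing one donor panel
        rec_rows = [r for ident in recipient for r in _hap_rows(aln, ident)]
        rec_group = None
    else:
        rec_rows = _hap_rows(aln, recipient)
        rec_group = donors.assignment.get(recipient)
        if rec_group is None:
            # recipient may be registered at haplotype level
            for ident, g in donors.assignment.items():
                if set(_hap_rows(aln, ident)) & set(rec_rows):
                    rec_group = g
                    break
    panel_rows, codes, groups = _donor_panel(
        aln, donors, set(rec_rows), leave_one_out, rec_group)
    if set(rec_rows) & set(panel_rows):
        raise ValueError(f"recipient {recipient!r} appears among its own donors")
    results = []
    for chrom in aln.chromosomes():
        mask = aln.chrom_mask(chrom)
        res = _forward_backward(
            aln.haplotypes[np.ix_(panel_rows, np.flatnonzero(mask))],
            aln.haplotypes[np.ix_(rec_rows, np.flatnonzero(mask))],
            cM[mask], params, codes, len(groups), keep_alphas=keep_alphas)
        results.append((chrom, mask, res))
    return rec_rows, panel_rows, codes, groups, results


def paint(aln: HaplotypeAlignment, donors: GroupAssignment, recipient: str,
          params: CopyingParams, leave_one_out: bool = True) -> PaintingSummary:
    """Painting profile of one recipient: expected copied cM and segments per group.

    Both haplotypes of a diploid recipient are painted and summed.  Under
    ``leave_one_out`` the recipient's own haplotypes are excluded, so its
    group donates n_k - 1 individuals.
    """
    _, _, _, groups, results = _paint_batch(aln, donors, recipient, params,
                                            leave_one_out)
    copied = pd.DataFrame(0.0, index=[c for c, _, _ in results], columns=groups)
    segs = pd.Series(0.0, index=groups)
    sites = pd.Series(0, index=[c for c, _, _ in results], dtype=int)
    for chrom, mask, res in results:
        copied.loc[chrom] = res.copied_cM.sum(axis=0)
        segs += pd.Series((res.first_site_group + res.switch_to_group).sum(axis=0),
                          index=groups)
        sites.loc[chrom] = int(mask.sum())
    return PaintingSummary(
        recipient=recipient,
        donor_groups=list(groups),
        copied_cM=copied.sum(axis=0),
        expected_segments=segs,
        per_chrom_cM=copied,
        chrom_sites=sites,
    )


def average_segment_size(summary: PaintingSummary) -> float:
    """Total copied cM over total expected segments (larger = less diverse)."""
    total_seg = float(summary.expected_segments.sum())
    if total_seg <= 0:
        raise ValueError("painting summary has no expected segments")
    return float(summary.copied_cM.sum()) / total_seg


def fit_copying_params(aln: HaplotypeAlignment, donors: GroupAssignment,
                       recipients: list[str], n_em_steps: int = 10,
                       init: CopyingParams | None = None) -> CopyingParams:
    """Jointly re-estimate switch and emission rates by E-M over recipients.

    Each E-M step runs forward-backward for every recipient (self excluded
    from its donors), accumulates expected switch counts per inter-site gap
    and expected allele mismatches, and maximizes the expected complete-data
    log-likelihood in both parameters.  The observed-data log-likelihood is
    non-decreasing across steps.
    """
    if n_em_steps < 1:
        raise ValueError("n_em_steps must be >= 1")
    cM = aln.require_cM()
    total_cM = sum(float(np.ptp(cM[aln.chrom_mask(c)])) for c in aln.chromosomes())
    if total_cM <= 0:
        raise ValueError("alignment has zero genetic length")
    n_donor_hap = sum(len(_hap_rows(aln, i)) for i in donors.assignment)
    if n_donor_hap < 1:
        raise ValueError("need at least one donor haplotype")
    if init is None:
        params = CopyingParams(switch_rate=100.0 * n_donor_hap / total_cM,
                               emission_mismatch=0.01)
    else:
        params = init

    last_ll = -np.inf
    for step in range(n_em_steps):
        gap_list, nsw_list, ntrial_list = [], [], []
        mismatch_total = 0.0
        obs_total = 0
        ll = 0.0
        for recipient in recipients:
            _, _, _, _, results = _paint_batch(aln, donors, recipient, params,
                                               leave_one_out=True)
            for chrom, mask, res in results:
                R = res.switch_prob.shape[0]
                gaps = np.diff(cM[mask])
                gap_list.append(gaps)
                nsw_list.append(res.switch_prob.sum(axis=0))
                ntrial_list.append(np.full(len(gaps), R))
                mismatch_total += res.mismatch_exp.sum()
                obs_total += R * res.n_sites
                ll += res.loglik.sum()
        if ll < last_ll - 1e-6:
            logger.warning("E-M log-likelihood decreased at step %d", step)
        last_ll = ll

        gaps = np.concatenate(gap_list)
        nsw = np.concatenate(nsw_list)
        ntr = np.concatenate(ntrial_list)
        pos = gaps > 0
        gaps, nsw, ntr = gaps[pos], nsw[pos], ntr[pos]

        def neg_q(log10_r: float) -> float:
            r = 10.0 ** log10_r
            stay = np.exp(-r * gaps / 100.0)
            stay = np.clip(stay, 1e-300, 1 - 1e-12)
            return -float(np.sum(nsw * np.log1p(-stay) + (ntr - nsw) * np.log(stay)))

        opt = minimize_scalar(neg_q, bounds=(-3, 4), method="bounded")
        new_rate = float(10.0 ** opt.x)
        new_emis = float(np.clip(mismatch_total / max(obs_total, 1), 1e-9, 0.499))
        params = CopyingParams(switch_rate=new_rate, emission_mismatch=new_emis)
    return params


def em_loglik_trace(aln: HaplotypeAlignment, donors: GroupAssignment,
                    recipients: list[str], n_em_steps: int = 10) -> list[float]:
    """Observed-data log-likelihood after each E-M parameter update."""
    cM = aln.require_cM()
    total_cM = sum(float(np.ptp(cM[aln.chrom_mask(c)])) for c in aln.chromosomes())
    n_donor_hap = sum(len(_hap_rows(aln, i)) for i in donors.assignment)
    params = CopyingParams(switch_rate=100.0 * n_donor_hap / total_cM,
                           emission_mismatch=0.01)
    trace = []
    for _ in range(n_em_steps):
        params = fit_copying_params(aln, donors, recipients, n_em_steps=1,
                                    init=params)
        ll = 0.0
        for recipient in recipients:
            _, _, _, _, results = _paint_batch(aln, donors, recipient, params,
                                               leave_one_out=True)
            ll += sum(res.loglik.sum() for _, _, res in results)
        trace.append(float(ll))
    return trace


def posterior_marginals(aln: HaplotypeAlignment, donors: GroupAssignment,
                        recipient: str, params: CopyingParams,
                        leave_one_out: bool = True) -> dict:
    """Per-site posterior copying probabilities over donor haplotypes.

    Returns chrom -> (R, S, D) arrays plus donor row order; used by tests
    against the exhaustive-path oracle and by Monte-Carlo checks.
    """
    rec_rows, panel_rows, codes, groups, results = _paint_batch(
        aln, donors, recipient, params, leave_one_out, keep_alphas=True)
    out = {}
    cM = aln.require_cM()
    for chrom, mask, res in results:
        donor_H = aln.haplotypes[np.ix_(panel_rows, np.flatnonzero(mask))]
        obs = aln.haplotypes[np.ix_(rec_rows, np.flatnonzero(mask))]
        D, S = donor_H.shape
        R = obs.shape[0]
        e = max(params.emission_mismatch, 1e-12)
        stay = res.stay
        gam = np.empty((R, S, D))
        beta = np.ones((R, D))
        g = res.alphas[S - 1] * beta
        gam[:, S - 1] = g / g.sum(axis=1, keepdims=True)
        for t in range(S - 2, -1, -1):
            match = obs[:, t + 1][:, None] == donor_H[None, :, t + 1]
            v = np.where(match, 1 - e, e) * beta
            mixed = stay[t] * v + (1 - stay[t]) / D * v.sum(axis=1, keepdims=True)
            ct = (res.alphas[t] * mixed).sum(axis=1, keepdims=True)
            beta = mixed / ct
            g = res.alphas[t] * beta
            gam[:, t] = g / g.sum(axis=1, keepdims=True)
        out[chrom] = {"gamma": gam, "donor_rows": panel_rows,
                      "donor_groups": [groups[c] for c in codes]}
    return out


def sample_paths(aln: HaplotypeAlignment, donors: GroupAssignment,
                 recipient, params: CopyingParams, n_samples: int,
                 seed: int | np.random.Generator = 0,
                 leave_one_out: bool = True) -> PaintingPathSample:
    """Draw donor paths from the copying posterior by backward sampling.

    ``recipient`` may be a single id or a list of ids painted jointly
    against one shared donor panel (with every listed recipient excluded
    from the donors).  Over many samples the per-site sampled group
    frequencies converge to the forward-backward marginals.  Labels are
    reported at donor-group level.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec_rows, panel_rows, codes, groups, results = _paint_batch(
        aln, donors, recipient, params, leave_one_out, keep_alphas=True)
    recipients = list(recipient) if isinstance(recipient, (list, tuple)) else [recipient]
    cM = aln.require_cM()
    sample = PaintingPathSample(groups=list(groups), recipients=recipients,
                                n_samples=n_samples)
    for chrom, mask, res in results:
        S = res.n_sites
        R = res.alphas.shape[1]
        D = res.alphas.shape[2]
        stay = res.stay
        paths = np.empty((R, n_samples, S), dtype=np.int16)
        cum = np.cumsum(res.alphas[S - 1], axis=1)
        u = rng.random((R, n_samples))
        cur = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
        paths[:, :, S - 1] = cur
        for t in range(S - 2, -1, -1):
            a = res.alphas[t]                        # (R, D)
            a_next = np.take_along_axis(a, cur, axis=1)   # (R, n_samples)
            s = stay[t]
            w_keep = s * a_next / (s * a_next + (1.0 - s) / D)
            keep = rng.random((R, n_samples)) < w_keep
            cum = np.cumsum(a, axis=1)
            u = rng.random((R, n_samples))
            fresh = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
            cur = np.where(keep, cur, fresh)
            paths[:, :, t] = cur
        sample.labels[chrom] = np.asarray(codes)[paths].astype(np.int16)
        sample.cM[chrom] = cM[mask].copy()
    return sample


def paint_group(aln: HaplotypeAlignment, donors: GroupAssignment,
                recipients: list[str], params: CopyingParams,
                leave_one_out: bool = True) -> pd.DataFrame:
    """Painting profiles for several recipients (rows), equally weighted."""
    rows = {}
    for r in recipients:
        rows[r] = paint(aln, donors, r, params, leave_one_out).profile
    return pd.DataFrame(rows).T
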