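"""Hierarchical Bayesian differential expression for 11-plex TMT data.

Reporter-ion intensities are first expressed as log2 ratios to the plex's
pooled global-mix channel.  The observation model for a ratio ``y`` of
protein ``p`` measured under label ``l`` (one (plex, channel) pair) is

    y = beta[p, l] + b[l] + eps,   eps ~ Normal(0, sigma_p^2)

with priors beta ~ Normal(0, nu^2), label bias b ~ Normal(0, tau^2) pooled
over all proteins (changing and unchanging), sigma_p^2 ~ InvGamma(a0, b0),
and a half-Normal(0, 0.5) hyperprior on tau updated by a Metropolis step.
The posterior is explored by a blocked Gibbs sampler run as several
independent chains; convergence is checked with the Gelman-Rubin statistic
(threshold 1.05).  Drug-induced differential expression is the per-draw
difference beta[treated] - beta[control], in which the global-mix
denominator cancels; replicates are combined by Bayesian updating
(precision-weighted Gaussian products) and effect sizes are Cohen's d
between the treated and control posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datamodel import AbundanceCube, PlexDesign, PsmRecord

logger = logging.getLogger(__name__)

DEFAULT_D_THRESHOLDS = {6: 1.50, 5: 1.75, 4: 2.25, 3: 3.38}


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------

def razor_protein_assignment(psms: list[PsmRecord]) -> dict[str, str]:
    """Map each PSM id to a single protein by razor assignment.

    Shared peptides go to the candidate protein with the most distinct
    peptides over the whole dataset (ties broken by protein id).
    """
    peptide_counts: dict[str, set] = {}
    for psm in psms:
        for p in psm.protein_ids:
            peptide_counts.setdefault(p, set()).add(psm.peptide_sequence)
    assignment = {}
    for psm in psms:
        assignment[psm.psm_id] = max(
            psm.protein_ids, key=lambda p: (len(peptide_counts[p]), p))
    return assignment


def psm_log_ratios(psms: list[PsmRecord], designs: list[PlexDesign]) -> pd.DataFrame:
    """log2 channel/global-mix ratios, one row per PSM x non-mix channel.

    PSMs whose mix intensity is <= 0, and individual channels with intensity
    <= 0, are dropped; the count is logged and attached as ``df.attrs``.
    """
    design_by_id = {d.plex_id: d for d in designs}
    assignment = razor_protein_assignment(psms)
    rows = []
    n_dropped = 0
    for psm in psms:
        design = design_by_id.get(psm.plex_id)
        if design is None:
            raise ValueError(f"PSM {psm.psm_id}: unknown plex {psm.plex_id!r}")
        mix = psm.intensities[design.mix_channel]
        if mix <= 0:
            n_dropped += 1
            continue
        protein = assignment[psm.psm_id]
        for ch, value in enumerate(psm.intensities):
            if ch == design.mix_channel:
                continue
            if value <= 0:
                n_dropped += 1
                continue
            rows.append((protein, psm.plex_id, ch + 1, psm.peptide_sequence,
                         np.log2(value / mix)))
    df = pd.DataFrame(rows, columns=["protein", "plex", "channel", "peptide", "ratio"])
    df.attrs["n_dropped"] = n_dropped
    if n_dropped:
        logger.info("psm_log_ratios: dropped %d non-positive intensities", n_dropped)
    return df


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class DeRecord:
    """Treated-minus-control log2 differential expression of one protein."""

    protein: str
    time_s: float
    fraction: str
    mean: float
    sd: float
    n_replicates: int = 1
    cohens_d: float = 0.0
    significant: bool = False
    # per-replicate treated/control posterior summaries feeding Cohen's d
    treated: tuple[float, float] | None = None
    control: tuple[float, float] | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.mean - 1.96 * self.sd, self.mean + 1.96 * self.sd)


def records_frame(records: list[DeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        lo, hi = r.ci95
        rows.append({"protein": r.protein, "time_s": r.time_s, "fraction": r.fraction,
                     "mean": r.mean, "sd": r.sd, "ci95_low": lo, "ci95_high": hi,
                     "cohens_d": r.cohens_d, "n_replicates": r.n_replicates,
                     "significant": r.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The hierarchical model
# ---------------------------------------------------------------------------

class TmtHierarchicalModel(BaseEstimator):
    """Gibbs-sampled hierarchical model for TMT log2 mix ratios.

    Parameters
    ----------
    n_chains : independent MCMC chains (>= 2; Gelman-Rubin needs several).
    n_steps : sweeps per chain; the first ``burn_in`` fraction is discarded.
    nu : prior sd of the per-(protein, label) expression parameters (log2),
        or None (default) to sample a per-protein scale nu_p^2 under an
        InvGamma(2, 0.5) hyperprior.  The per-protein scale lets changing
        proteins carry large expression parameters while the pooled mass of
        unchanging proteins identifies the per-label bias (a global Gaussian
        scale would instead collapse and push planted effects into the
        per-protein noise variance).
    tau : fixed label-bias prior sd, or None to estimate it under a
        half-Normal(0, 0.5) hyperprior via a Metropolis step.
    sigma2_prior_shape, sigma2_prior_scale : InvGamma prior on the
        per-protein reporter noise variance.
    sigma_fixed : fix the noise sd instead of sampling it (conjugate checks).
    sd_floor : lower bound applied to all reported posterior sds.
    random_state : seed for the sampler.

    Attributes (after ``fit``)
    --------------------------
    posteriors_ : DataFrame (protein, plex, channel, mean, sd) of beta.
    bias_ : DataFrame (plex, channel, mean, sd) of label biases.
    convergence_ : DataFrame (parameter, rhat, converged) for every beta,
        bias and sigma.
    diff_records_ : list of per-replicate ``DeRecord`` built per draw.
    """

    def __init__(self, n_chains=5, n_steps=2000, burn_in=0.25, nu=None,
                 tau=None, sigma2_prior_shape=2.0, sigma2_prior_scale=0.5,
                 nu2_prior_shape=2.0, nu2_prior_scale=0.5,
                 sigma_fixed=None, sd_floor=1e-3, rhat_threshold=1.05,
                 random_state=0):
        self.n_chains = n_chains
        self.n_steps = n_steps
        self.burn_in = burn_in
        self.nu = nu
        self.nu2_prior_shape = nu2_prior_shape
        self.nu2_prior_scale = nu2_prior_scale
        self.tau = tau
        self.sigma2_prior_shape = sigma2_prior_shape
        self.sigma2_prior_scale = sigma2_prior_scale
        self.sigma_fixed = sigma_fixed
        self.sd_floor = sd_floor
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _index(self, ratios: pd.DataFrame, designs: list[PlexDesign]):
        proteins = np.array(sorted(ratios["protein"].unique()))
        p_ix = {p: i for i, p in enumerate(proteins)}
        labels = sorted({(r.plex, int(r.channel)) for r in
                         ratios[["plex", "channel"]].itertuples(index=False)})
        l_ix = {l: i for i, l in enumerate(labels)}
        pi = ratios["protein"].map(p_ix).to_numpy()
        li = np.fromiter((l_ix[(pl, int(ch))] for pl, ch in
                          zip(ratios["plex"], ratios["channel"])),
                         dtype=np.int64, count=len(ratios))
        keys = pi * len(labels) + li
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        uniq, first = np.unique(keys_sorted, return_index=True)
        g_of_row = np.searchsorted(uniq, keys)
        y = ratios["ratio"].to_numpy(dtype=float)
        n_g = np.bincount(g_of_row, minlength=len(uniq)).astype(float)
        s1_g = np.bincount(g_of_row, weights=y, minlength=len(uniq))
        s2_g = np.bincount(g_of_row, weights=y * y, minlength=len(uniq))
        g_protein = (uniq // len(labels)).astype(np.int64)
        g_label = (uniq % len(labels)).astype(np.int64)
        group_lookup = {(int(p), int(l)): g for g, (p, l)
                        in enumerate(zip(g_protein, g_label))}

        # matched treated/control group pairs per (protein, plex, time)
        design_by_id = {d.plex_id: d for d in designs}
        pair_gt, pair_gc, pair_meta = [], [], []
        for plex_id, design in design_by_id.items():
            t_ch = {}
            c_ch = {}
            for ch, a in enumerate(design.channel_map, start=1):
                if a.condition == "treated":
                    t_ch[a.time_s] = ch
                elif a.condition == "control":
                    c_ch[a.time_s] = ch
            for t in design.time_points_s:
                lt = l_ix.get((plex_id, t_ch[t]))
                lc = l_ix.get((plex_id, c_ch[t]))
                if lt is None or lc is None:
                    continue
                for p_i in range(len(proteins)):
                    gt = group_lookup.get((p_i, lt))
                    gc = group_lookup.get((p_i, lc))
                    if gt is None or gc is None:
                        continue
                    pair_gt.append(gt)
                    pair_gc.append(gc)
                    pair_meta.append((proteins[p_i], design.fraction, t,
                                      design.bio_replicate, design.tech_replicate,
                                      plex_id))
        return (proteins, labels, n_g, s1_g, s2_g, g_protein, g_label,
                np.array(pair_gt, dtype=np.int64), np.array(pair_gc, dtype=np.int64),
                pair_meta)

    def fit(self, ratios: pd.DataFrame, designs: list[PlexDesign]):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (Gelman-Rubin undefined otherwise)")
        if len(ratios) == 0:
            raise ValueError("no observations")
        (proteins, labels, n_g, s1_g, s2_g, g_protein, g_label,
         pair_gt, pair_gc, pair_meta) = self._index(ratios, designs)
        G, L, P = len(n_g), len(labels), len(proteins)
        n_burn = int(self.burn_in * self.n_steps)
        n_keep = self.n_steps - n_burn
        if n_keep < 2:
            raise ValueError("too few post-burn-in steps")

        a0, b0 = float(self.sigma2_prior_shape), float(self.sigma2_prior_scale)
        an, bn = float(self.nu2_prior_shape), float(self.nu2_prior_scale)
        n_p = np.bincount(g_protein, weights=n_g, minlength=P)
        ybar_g = s1_g / n_g

        ss = np.random.SeedSequence(self.random_state)
        chain_seeds = ss.spawn(self.n_chains)

        def run_chain(child):
            rng = np.random.default_rng(child)
            beta = s1_g / n_g
            b = np.zeros(L)
            if self.sigma_fixed is not None:
                sigma2 = np.full(P, float(self.sigma_fixed) ** 2)
            else:
                rss0 = np.bincount(g_protein, weights=s2_g - s1_g**2 / n_g, minlength=P)
                sigma2 = np.clip((b0 + 0.5 * rss0) / (a0 + 0.5 * n_p), 1e-6, None)
            tau = float(self.tau) if self.tau is not None else 0.3
            est_tau = self.tau is None
            est_nu = self.nu is None
            g_per_p = np.bincount(g_protein, minlength=P).astype(float)
            if est_nu:
                ssb = np.bincount(g_protein, weights=beta**2, minlength=P)
                nu2_p = np.clip(ssb / np.maximum(g_per_p, 1.0), 1e-4, None)
            else:
                nu2_p = np.full(P, float(self.nu) ** 2)

            acc = {k: np.zeros(shape) for k, shape in [
                ("beta_s", G), ("beta_q", G), ("b_s", L), ("b_q", L),
                ("sig_s", P), ("sig_q", P), ("d_s", len(pair_gt)),
                ("d_q", len(pair_gt))]}
            est_sigma = self.sigma_fixed is None
            # collapsed within-group sufficient stats (do not depend on beta)
            w_rss_p = np.bincount(g_protein, weights=s2_g - s1_g**2 / n_g, minlength=P)
            w_df_p = np.bincount(g_protein, weights=n_g - 1.0, minlength=P)
            # proteins with zero within-group df (single-PSM groups only)
            # cannot separate reporter noise from expression spread; they
            # share the pooled noise variance instead of a private sigma_p
            no_within = w_df_p <= 0
            pool_df = float(w_df_p.sum())
            pool_rss = float(w_rss_p.sum())

            def scales_logpost(sig2, n2, b_cur):
                """log p(sigma^2, nu^2 | b, y) with beta integrated out,
                per protein (unnormalised), plus log-scale Jacobians."""
                v_g = sig2[g_protein] / n_g + n2[g_protein]
                resid = ybar_g - b_cur[g_label]
                between = np.bincount(
                    g_protein, weights=np.log(v_g) + resid**2 / v_g, minlength=P)
                lp = -0.5 * between
                lp -= 0.5 * (w_df_p * np.log(sig2) + w_rss_p / sig2)
                if est_sigma:
                    lp += -(a0 + 1.0) * np.log(sig2) - b0 / sig2 + np.log(sig2)
                if est_nu:
                    lp += -(an + 1.0) * np.log(n2) - bn / n2 + np.log(n2)
                return lp

            for step in range(self.n_steps):
                nu2_g = nu2_p[g_protein]
                inv_s2 = 1.0 / sigma2[g_protein]
                # b | y, sigma, nu, tau  (beta collapsed out: the group mean
                # ybar_g | b is Normal(b_l, sigma_p^2/n_g + nu_p^2))
                w_g = 1.0 / (1.0 / (n_g * inv_s2) + nu2_g)
                a_l = np.bincount(g_label, weights=w_g * ybar_g, minlength=L)
                p_l = np.bincount(g_label, weights=w_g, minlength=L)
                prec_b = p_l + 1.0 / tau**2
                b = a_l / prec_b + rng.standard_normal(L) / np.sqrt(prec_b)
                # (sigma_p^2, nu_p^2) | b, y with beta collapsed out: joint
                # Metropolis on the log scales; collapsing beta removes the
                # slow random walk along the sigma/nu trade-off for proteins
                # with single-observation groups
                if est_sigma or est_nu:
                    if est_sigma and pool_df > 0:
                        # pooled reporter noise, conjugate from all within-
                        # group residuals; assigned to zero-within-df proteins
                        sigma0_sq = (b0 + 0.5 * pool_rss) / \
                            rng.standard_gamma(a0 + 0.5 * pool_df)
                        sigma2 = np.where(no_within, sigma0_sq, sigma2)
                    # proposal scales tuned to the local curvature ~ sqrt(2/df)
                    step_s = np.clip(2.4 * np.sqrt(2.0 / np.maximum(n_p, 2.0)),
                                     0.05, 0.8)
                    step_n = np.clip(2.4 * np.sqrt(2.0 / np.maximum(g_per_p, 2.0)),
                                     0.05, 0.8)
                    lp0 = scales_logpost(sigma2, nu2_p, b)
                    for _ in range(3):
                        if est_sigma:
                            jump = step_s * rng.standard_normal(P)
                            jump[no_within] = 0.0  # sigma fixed to the pool
                            prop_s = sigma2 * np.exp(jump)
                        else:
                            prop_s = sigma2
                        prop_n = nu2_p * np.exp(step_n * rng.standard_normal(P)) \
                            if est_nu else nu2_p
                        lp1 = scales_logpost(prop_s, prop_n, b)
                        accept = np.log(rng.random(P)) < lp1 - lp0
                        if est_sigma:
                            sigma2 = np.where(accept, prop_s, sigma2)
                        if est_nu:
                            nu2_p = np.where(accept, prop_n, nu2_p)
                        lp0 = np.where(accept, lp1, lp0)
                    nu2_g = nu2_p[g_protein]
                    inv_s2 = 1.0 / sigma2[g_protein]
                # beta | b, sigma, nu, y
                prec = n_g * inv_s2 + 1.0 / nu2_g
                mean = (s1_g - n_g * b[g_label]) * inv_s2 / prec
                beta = mean + rng.standard_normal(G) / np.sqrt(prec)
                # tau | b  (Metropolis on log tau, half-Normal(0, 0.5) prior)
                if est_tau:
                    sb2 = float(b @ b)
                    def logp(lt):
                        t = np.exp(lt)
                        return (1.0 - L) * lt - sb2 / (2 * t * t) - t * t / 0.5
                    lt0 = np.log(tau)
                    lt1 = lt0 + 0.2 * rng.standard_normal()
                    if np.log(rng.random()) < logp(lt1) - logp(lt0):
                        tau = float(np.exp(lt1))
                if step >= n_burn:
                    acc["beta_s"] += beta; acc["beta_q"] += beta**2
                    acc["b_s"] += b; acc["b_q"] += b**2
                    sig = np.sqrt(sigma2)
                    acc["sig_s"] += sig; acc["sig_q"] += sig**2
                    if len(pair_gt):
                        d = beta[pair_gt] - beta[pair_gc]
                        acc["d_s"] += d; acc["d_q"] += d**2
            return acc

        chains = [run_chain(child) for child in chain_seeds]

        def pooled(prefix):
            s = sum(c[prefix + "_s"] for c in chains)
            q = sum(c[prefix + "_q"] for c in chains)
            n = n_keep * self.n_chains
            mean = s / n
            var = np.clip(q / n - mean**2, 0.0, None)
            return mean, np.maximum(np.sqrt(var), self.sd_floor)

        def rhat(prefix):
            n = float(n_keep)
            means = np.stack([c[prefix + "_s"] / n for c in chains])
            variances = np.stack([
                np.clip(c[prefix + "_q"] / n - (c[prefix + "_s"] / n) ** 2, 0.0, None)
                * n / (n - 1.0) for c in chains])
            w = variances.mean(axis=0)
            bvar = means.var(axis=0, ddof=1) * n
            v = (n - 1.0) / n * w + bvar / n
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.sqrt(v / w)
            return np.where(w <= 0, 1.0, r)

        beta_mean, beta_sd = pooled("beta")
        b_mean, b_sd = pooled("b")
        sig_mean, sig_sd = pooled("sig")

        self.posteriors_ = pd.DataFrame({
            "protein": proteins[g_protein],
            "plex": [labels[l][0] for l in g_label],
            "channel": [labels[l][1] for l in g_label],
            "mean": beta_mean, "sd": beta_sd,
            "n_effective_draws": n_keep * self.n_chains,
        })
        self.bias_ = pd.DataFrame({
            "plex": [l[0] for l in labels], "channel": [l[1] for l in labels],
            "mean": b_mean, "sd": b_sd,
        })
        rows = []
        for name, values in [("beta", rhat("beta")), ("bias", rhat("b")),
                             ("sigma", rhat("sig"))]:
            for i, r in enumerate(values):
                rows.append((f"{name}[{i}]", float(r)))
        self.convergence_ = pd.DataFrame(rows, columns=["parameter", "rhat"])
        self.convergence_["n_chains"] = self.n_chains
        self.convergence_["n_steps"] = self.n_steps
        self.convergence_["converged"] = self.convergence_["rhat"] < self.rhat_threshold

        if len(pair_gt):
            d_mean, d_sd = pooled("d")
        else:
            d_mean = d_sd = np.array([])
        self.diff_records_ = []
        lookup_mean = beta_mean
        lookup_sd = beta_sd
        self._diff_meta_ = pair_meta
        for i, (protein, fraction, t, bio, tech, plex) in enumerate(pair_meta):
            self.diff_records_.append(DeRecord(
                protein=protein, time_s=t, fraction=fraction,
                mean=float(d_mean[i]), sd=float(max(d_sd[i], self.sd_floor)),
                n_replicates=1,
                treated=(float(lookup_mean[pair_gt[i]]), float(lookup_sd[pair_gt[i]])),
                control=(float(lookup_mean[pair_gc[i]]), float(lookup_sd[pair_gc[i]])),
            ))
            # bio/tech replicate ids kept alongside for combination
        self._diff_replicates_ = [(m[3], m[4]) for m in pair_meta]
        self.max_rhat_ = float(self.convergence_["rhat"].max())
        return self


def fit_hierarchical_model(ratios: pd.DataFrame, designs: list[PlexDesign],
                           n_chains: int = 5, n_steps: int = 2000,
                           burn_in: float = 0.25, seed: int = 0,
                           **kwargs):
    """Functional wrapper: returns (posteriors, bias posteriors, convergence)."""
    model = TmtHierarchicalModel(n_chains=n_chains, n_steps=n_steps,
                                 burn_in=burn_in, random_state=seed, **kwargs)
    model.fit(ratios, designs)
    return model.posteriors_, model.bias_, model.convergence_


# ---------------------------------------------------------------------------
# Treated minus control, replicate combination, effect sizes
# ---------------------------------------------------------------------------

def treated_minus_control(model_or_posteriors, designs: list[PlexDesign] | None = None,
                          sd_floor: float = 1e-3) -> list[DeRecord]:
    """Per-replicate treated-minus-control records.

    Given a fitted :class:`TmtHierarchicalModel`, the differences were formed
    per MCMC draw (respecting posterior correlation) and are returned
    directly.  Given a posterior summary DataFrame, the Gaussian-difference
    closed form (independent posteriors) is used instead.
    """
    if isinstance(model_or_posteriors, TmtHierarchicalModel):
        return list(model_or_posteriors.diff_records_)
    posteriors = model_or_posteriors
    if designs is None:
        raise ValueError("designs required when passing posterior summaries")
    records = []
    by_key = {(r.protein, r.plex, int(r.channel)): (r.mean, r.sd)
              for r in posteriors.itertuples(index=False)}
    for design in designs:
        t_ch, c_ch = {}, {}
        for ch, a in enumerate(design.channel_map, start=1):
            if a.condition == "treated":
                t_ch[a.time_s] = ch
            elif a.condition == "control":
                c_ch[a.time_s] = ch
        if set(t_ch) != set(c_ch):
            raise ValueError(f"plex {design.plex_id}: unmatched treated/control pair")
        for protein in posteriors.loc[posteriors["plex"] == design.plex_id,
                                      "protein"].unique():
            for t in design.time_points_s:
                treated = by_key.get((protein, design.plex_id, t_ch[t]))
                control = by_key.get((protein, design.plex_id, c_ch[t]))
                if treated is None or control is None:
                    continue
                mean = treated[0] - control[0]
                sd = max(float(np.hypot(treated[1], control[1])), sd_floor)
                records.append(DeRecord(protein=protein, time_s=t,
                                        fraction=design.fraction, mean=mean, sd=sd,
                                        treated=treated, control=control))
    return records


def combine_biological_replicates(records: list[DeRecord]) -> DeRecord:
    """Bayesian updating: precision-weighted Gaussian product of replicates."""
    if not records:
        raise ValueError("no records to combine")
    if len(records) == 1:
        return replace(records[0], n_replicates=records[0].n_replicates)
    w = np.array([1.0 / r.sd**2 for r in records])
    mean = float(np.sum(w * [r.mean for r in records]) / w.sum())
    sd = float(1.0 / np.sqrt(w.sum()))

    def combine_side(sides):
        if any(s is None for s in sides):
            return None
        ws = np.array([1.0 / s[1] ** 2 for s in sides])
        return (float(np.sum(ws * [s[0] for s in sides]) / ws.sum()),
                float(1.0 / np.sqrt(ws.sum())))

    return DeRecord(protein=records[0].protein, time_s=records[0].time_s,
                    fraction=records[0].fraction, mean=mean, sd=sd,
                    n_replicates=int(sum(r.n_replicates for r in records)),
                    treated=combine_side([r.treated for r in records]),
                    control=combine_side([r.control for r in records]))


def combine_technical_replicates(records: list[DeRecord]) -> DeRecord:
    """Average point estimates; add credible-interval extents in quadrature.

    With CI half-widths h_r over R technical replicates the combined
    half-width is sqrt(sum h_r^2) / R, so technical replicates contribute a
    single distribution to any further Bayesian updating.
    """
    if not records:
        raise ValueError("no records to combine")
    if len(records) == 1:
        return records[0]
    R = len(records)
    mean = float(np.mean([r.mean for r in records]))
    half_widths = np.array([1.96 * r.sd for r in records])
    half = float(np.sqrt(np.sum(half_widths**2)) / R)
    return replace(records[0], mean=mean, sd=half / 1.96, n_replicates=records[0].n_replicates)


def cohens_d(treated: tuple[float, float], control: tuple[float, float]) -> float:
    """d = |mu_T - mu_C| / sqrt((sd_T^2 + sd_C^2) / 2) between two Gaussians."""
    mu_t, sd_t = treated
    mu_c, sd_c = control
    denom = np.sqrt((sd_t**2 + sd_c**2) / 2.0)
    if denom == 0:
        return 0.0 if mu_t == mu_c else float("inf")
    return float(abs(mu_t - mu_c) / denom)


def min_detectable_effect(alpha: float = 0.05, power: float = 0.8, n: int = 3) -> float:
    """Smallest Cohen's d giving the requested power for a two-sided
    two-sample t-test with ``n`` observations per group (noncentral t)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = 2 * n - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)

    def achieved_power(d):
        ncp = d * np.sqrt(n / 2.0)
        value = (1.0 - stats.nct.cdf(t_crit, df, ncp)
                 + stats.nct.cdf(-t_crit, df, ncp))
        # the noncentral-t cdf underflows at extreme ncp where power -> 1
        return value if np.isfinite(value) else 1.0

    return float(optimize.brentq(lambda d: achieved_power(d) - power,
                                 1e-8, 50.0, xtol=1e-6))


@dataclass
class PowerSpec:
    """Significance criteria and the per-replicate-count d thresholds."""

    alpha: float = 0.05
    power: float = 0.8
    thresholds_by_n: dict = field(default_factory=lambda: dict(DEFAULT_D_THRESHOLDS))

    def threshold(self, n: int) -> float:
        if n in self.thresholds_by_n:
            return self.thresholds_by_n[n]
        return min_detectable_effect(self.alpha, self.power, max(n, 2))


def combine_by_protein_time(per_replicate: list[DeRecord],
                            replicate_ids: list | None = None) -> list[DeRecord]:
    """Combine per-replicate records into one record per
    (protein, fraction, time): technical replicates by quadrature first,
    then biological replicates by Bayesian updating.

    The combined record's Cohen's d compares the treated and control
    posterior locations on the single-replicate spread scale (the
    distribution sd, not the standard error of the combined mean), which is
    the convention the per-replicate-count threshold table presumes.
    """
    if replicate_ids is None:
        replicate_ids = [(i, 1) for i in range(len(per_replicate))]
    grouped: dict = {}
    for rec, (bio, tech) in zip(per_replicate, replicate_ids):
        grouped.setdefault((rec.protein, rec.fraction, rec.time_s), {}) \
               .setdefault(bio, []).append(rec)
    combined = []
    for (protein, fraction, t), by_bio in sorted(grouped.items()):
        bio_records = [combine_technical_replicates(v) for v in by_bio.values()]
        n = len(bio_records)
        rec = combine_biological_replicates(bio_records)
        rec.n_replicates = n
        if rec.treated is not None and rec.control is not None:
            # representative single-replicate spread: combined sd * sqrt(n)
            t_pop = (rec.treated[0], rec.treated[1] * np.sqrt(n))
            c_pop = (rec.control[0], rec.control[1] * np.sqrt(n))
            rec.cohens_d = cohens_d(t_pop, c_pop)
        else:
            rec.cohens_d = cohens_d((rec.mean, rec.sd * np.sqrt(n)), (0.0, rec.sd * np.sqrt(n)))
        combined.append(rec)
    return combined


def select_significant(records: list[DeRecord], spec: PowerSpec | None = None
                       ) -> list[DeRecord]:
    """Flag records whose effect size exceeds the replicate-count threshold;
    return records of proteins selected at >= 1 time point."""
    spec = spec or PowerSpec()
    for rec in records:
        rec.significant = rec.cohens_d > spec.threshold(rec.n_replicates)
    selected_proteins = {r.protein for r in records if r.significant}
    return [r for r in records if r.protein in selected_proteins]


def stratified_timecourse_pvalues(cube: AbundanceCube, spline_df: int = 3,
                                  n_permutations: int = 1000, seed: int = 0
                                  ) -> pd.DataFrame:
    """Per-entity time-course p-values computed separately per
    replicate-count stratum, then pooled into one Benjamini-Hochberg pass."""
    from .timecourse import benjamini_hochberg, timecourse_significance

    patterns: dict[tuple, list] = {}
    for i, entity in enumerate(cube.entity_ids):
        present = tuple(~np.all(np.isnan(cube.values[i]), axis=(0, 1)))
        patterns.setdefault(present, []).append(entity)
    frames = []
    for present, entities in sorted(patterns.items()):
        n_rep = sum(present)
        if n_rep < 2:
            continue
        sub = cube.restrict_entities(entities)
        rep_ix = [j for j, keep in enumerate(present) if keep]
        sub = AbundanceCube(sub.entity_ids, sub.fractions, sub.time_points_s,
                            [sub.replicates[j] for j in rep_ix],
                            sub.values[:, :, :, rep_ix])
        res = timecourse_significance(sub, spline_df=spline_df,
                                      n_permutations=n_permutations, seed=seed,
                                      compute_q=False)
        res["n_replicates"] = n_rep
        frames.append(res)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["q"] = benjamini_hochberg(pooled["p"].to_numpy())
    return pooled
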