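"""Liability-scale summaries and the replicated-simulation evaluator.

The liability residual variance is fixed at 1, so a locus with additive
effect a and dominance effect d contributes VG = a^2/2 + d^2 (the F2
variances of the additive and dominance codes are 1/2 and 1) and the
broad-sense heritability of the liability is H = VG / (VG + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_map import F2_PRIOR, GeneticMap
from .liability import CofactorSpec, design_matrix, penetrance


def locus_heritability(a: float, d: float = 0.0):
    """(VG, VP, H) for a single locus: VG = a^2/2 + d^2, VP = VG + 1."""
    vg = 0.5 * a**2 + d**2
    vp = vg + 1.0
    return vg, vp, vg / vp


def total_heritability(effects, cofactors=()) -> float:
    """Overall liability variance proportion from all loci and co-factors.

    Loci are assumed unlinked, so VG = sum_k (a_k^2/2 + d_k^2) plus
    beta^2 Var(X) per co-factor, and H = VG / (VG + 1).  ``cofactors``
    entries are (beta, var_x) pairs or :class:`CofactorSpec`.
    """
    vg = sum(0.5 * a**2 + d**2 for a, d in effects)
    for cof in cofactors:
        if isinstance(cof, CofactorSpec):
            vg += cof.beta**2 * cof.prior_variance
        else:
            beta, var_x = cof
            vg += beta**2 * var_x
    return vg / (vg + 1.0)


def expected_genotype_freqs(a: float, d: float, prior=F2_PRIOR, link: str = "probit"):
    """Post-selection genotype frequencies at a viability locus.

    pibar = sum_g prior_g * Phi(H_g (a, d)) is the population survival
    probability; each genotype frequency among survivors is
    prior_g * Phi(H_g (a, d)) / pibar.  Returns (freqs, pibar).
    """
    H = design_matrix("additive_dominance")
    prior = np.asarray(prior, dtype=float)
    pen = penetrance(H @ np.array([a, d]), link)
    num = prior * pen
    pibar = num.sum()
    return num / pibar, float(pibar)


def null_threshold(
    gmap: GeneticMap,
    n: int,
    n_replicates: int = 30,
    quantile: float = 0.95,
    seed: int = 0,
    cofactors: list[CofactorSpec] | None = None,
    **fit_params,
) -> float:
    """Empirical genome-wide LOD threshold under Mendelian segregation.

    Simulates ``n_replicates`` unselected populations, fits the full scan
    to each, records the genome-wide maximum LOD over all effects (loci
    and co-factors), and returns the requested empirical quantile.  The
    genome-wide maximum controls family-wise error for the whole scan.
    """
    from .glmm import fit_scan
    from .simulate import simulate_null

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    maxima = []
    for rep in range(n_replicates):
        genotypes, specs = simulate_null(gmap, n, seed + rep, cofactors)
        try:
            res = fit_scan(genotypes, cofactors=specs, **fit_params)
        except Exception as err:  # pragma: no cover - defensive
            import warnings

            warnings.warn(f"null replicate {rep} failed and was excluded: {err}")
            continue
        m = float(res.lod.max())
        if res.beta_lod.size:
            m = max(m, float(res.beta_lod.max()))
        maxima.append(m)
    return float(np.quantile(maxima, quantile))


def run_power_study(
    n_replicates: int = 30,
    seed: int = 1,
    threshold: float = 2.99,
    window_cM: float = 15.0,
    sim_config=None,
    **fit_params,
) -> pd.DataFrame:
    """Replicated simulate-and-fit power/false-positive study.

    Replicate r simulates a fresh selected population with seed
    ``seed + r`` (the default design when ``sim_config`` is None), fits
    the scan, and the pooled results are scored by :func:`power_fpr`.
    Per-replicate co-factor estimates are attached in attrs.
    """
    from .glmm import fit_scan
    from .simulate import SimConfig, simulate_selected_population

    results, betas = [], []
    effects = gmap = None
    for rep in range(n_replicates):
        base = sim_config or SimConfig()
        cfg = SimConfig(
            n_chromosomes=base.n_chromosomes, length_cM=base.length_cM,
            spacing_cM=base.spacing_cM, effects=list(base.effects),
            cofactors=list(base.cofactors), n_survivors=base.n_survivors,
            link=base.link, seed=seed + rep,
        )
        genotypes, cofactors, truth = simulate_selected_population(cfg)
        effects = truth.attrs["effects"]
        gmap = truth.attrs["map"]
        res = fit_scan(genotypes, cofactors=cofactors, **fit_params)
        results.append(res)
        betas.append(res.beta)
    table = power_fpr(
        results, effects, gmap.positions, threshold, window_cM,
        chromosomes=gmap.to_frame()["chromosome"].astype(str).tolist(),
    )
    table.attrs["beta_estimates"] = np.array(betas)
    table.attrs["true_betas"] = [spec.beta for spec in (sim_config or SimConfig()).cofactors]
    table.attrs["results"] = results
    return table


def power_fpr(
    replicates,
    truth: pd.DataFrame,
    positions: np.ndarray,
    threshold: float,
    window_cM: float = 15.0,
    chromosomes: list[str] | None = None,
) -> pd.DataFrame:
    """Detection power per true locus and the overall false-positive rate.

    A true locus counts as detected in a replicate when any marker
    strictly within ``window_cM`` of it (same chromosome) has LOD above
    ``threshold``; the strict boundary makes a 15 cM window at 5 cM
    marker spacing cover five markers (the true marker +/-2);
    the reported estimate is taken at the peak-LOD marker of the window.
    Any above-threshold marker outside every window is a false positive,
    and the rate divides the total count by replicates x (markers outside
    all windows).  Markers in overlapping windows belong to the nearest
    true locus.  ``replicates`` is a list of FitResult; LODs and
    estimates are taken effect-wise (max over additive/dominance LOD).

    Returns a table with one row per true locus (power %, mean and SD of
    the peak estimate) and the false-positive summary in ``attrs``.
    """
    positions = np.asarray(positions, dtype=float)
    p = len(positions)
    if chromosomes is None:
        chromosomes = ["1"] * p
    chromosomes = np.asarray(chromosomes, dtype=object)

    # assign each marker to the nearest in-window true locus, else -1
    assignment = np.full(p, -1)
    dist_best = np.full(p, np.inf)
    for t, row in truth.reset_index(drop=True).iterrows():
        on_chrom = chromosomes == str(row["chromosome"])
        dist = np.abs(positions - float(row["position_cM"]))
        hit = on_chrom & (dist < window_cM) & (dist < dist_best)
        assignment[hit] = t
        dist_best[hit] = dist[hit]

    n_rep = len(replicates)
    n_true = len(truth)
    detected = np.zeros(n_true, dtype=int)
    peak_estimates: list[list[float]] = [[] for _ in range(n_true)]
    false_positives = 0
    for res in replicates:
        lod = res.lod.max(axis=1)  # strongest effect at each marker
        exceed = lod > threshold
        false_positives += int(np.sum(exceed & (assignment == -1)))
        for t in range(n_true):
            in_win = assignment == t
            if np.any(exceed & in_win):
                detected[t] += 1
                peak = np.flatnonzero(in_win)[np.argmax(lod[in_win])]
                peak_estimates[t].append(float(res.gamma[peak, 0]))
    n_null_markers = int(np.sum(assignment == -1))
    table = pd.DataFrame(
        {
            "marker": truth["marker"].to_numpy(),
            "chromosome": truth["chromosome"].to_numpy(),
            "position_cM": truth["position_cM"].to_numpy(),
            "true_additive": truth["additive"].to_numpy(),
            "power_pct": 100.0 * detected / n_rep,
            "mean_estimate": [float(np.mean(e)) if e else np.nan for e in peak_estimates],
            "sd_estimate": [float(np.std(e, ddof=1)) if len(e) > 1 else np.nan for e in peak_estimates],
            "n_detected": detected,
        }
    )
    table.attrs["n_replicates"] = n_rep
    table.attrs["threshold"] = threshold
    table.attrs["window_cM"] = window_cM
    table.attrs["false_positives"] = false_positives
    table.attrs["n_null_tests"] = n_rep * n_null_markers
    table.attrs["fpr"] = false_positives / (n_rep * n_null_markers) if n_null_markers else np.nan
    return table
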