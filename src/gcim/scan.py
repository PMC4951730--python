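"""Genome-wide single-locus scan and peak selection.

The scan fits the polygenic background once (whole-marker kinship) or per
marker interval (part-marker kinship, with the two true markers flanking
the scanned position removed from K), then tests every true and pseudo
locus with the random-effect profiled REML or the fixed-effect GLS test.
All the peaks of the resulting -log10 p curve become multi-locus
candidates; no significance threshold is applied at this stage, so small
and linked effects survive into the second stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .genome import GeneticMap, GenotypeData, build_kinship
from .mixed_model import (
    _fixed_effect_stats,
    _newton_lambda_k,
    _projection_scalars,
    _random_effect_stats,
    fit_polygenic,
    wald_p,
)

__all__ = ["ScanResult", "CandidateSet", "genome_scan", "select_peaks"]

P_FLOOR = 1e-300


@dataclass
class ScanResult:
    """Per-locus scan statistics over the whole scan grid (map order)."""

    table: pd.DataFrame
    lambda0: float = np.nan       # polygenic ratio (whole-K mode)
    sigma2_polygenic: float = np.nan
    n_degenerate: int = 0         # monomorphic / collinear loci

    def __len__(self):
        return len(self.table)


@dataclass
class CandidateSet:
    """Scan-grid peak indices and their statistics, sorted by position."""

    indices: np.ndarray
    table: pd.DataFrame

    def __len__(self):
        return self.indices.size


def _scan_columns(y, X, Z, delta, U, lambda0, effect):
    """Test a block of loci (columns of Z) under one background fit."""
    D = delta * lambda0 + 1.0
    y_rot = U.T @ y
    X_rot = U.T @ X
    Z_rot = U.T @ Z
    nu = y.size - X.shape[1]
    theta, kappa, Q0, _, _ = _projection_scalars(y_rot, X_rot, Z_rot, D)
    theta = np.maximum(theta, 0.0)
    if effect == "random":
        lam, _ = _newton_lambda_k(theta, kappa, Q0, nu)
        gamma, gvar, sigma2, wald = _random_effect_stats(lam, theta, kappa, Q0, nu)
    elif effect == "fixed":
        gamma, gvar, sigma2, wald = _fixed_effect_stats(theta, kappa, Q0, nu)
        lam = np.full(theta.size, np.nan)
    else:
        raise ValueError(f"unknown effect model {effect!r}")
    degenerate = theta <= 1e-12 * max(Q0, 1.0)
    p = wald_p(wald)
    p = np.where(degenerate, 1.0, p)
    gamma = np.where(degenerate, 0.0, gamma)
    wald = np.where(degenerate, 0.0, wald)
    return lam, gamma, gvar, wald, p, int(degenerate.sum())


def genome_scan(
    geno: GenotypeData,
    gmap: GeneticMap,
    y,
    X=None,
    effect: str = "random",
    kinship: str = "whole",
    eig_cache: dict | None = None,
) -> ScanResult:
    """Scan every locus of the map, one at a time, against the polygenic background.

    ``geno`` must cover the scan grid of ``gmap`` with filled expected codes
    (see :func:`gcim.genome.fill_expected`). ``eig_cache`` optionally reuses
    kinship eigen-decompositions across scans of the same genotypes (they do
    not depend on the phenotype), which the part-marker mode and the
    phenotype-correction rescan exploit.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if geno.n_individuals != n:
        raise ValueError("phenotype and genotypes disagree on sample size")
    if geno.n_loci != gmap.n_loci or not np.array_equal(geno.names, gmap.name):
        raise ValueError("genotype columns must match the scan grid of the map")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if kinship not in ("whole", "part"):
        raise ValueError(f"unknown kinship mode {kinship!r}")
    if eig_cache is None:
        eig_cache = {}

    Z = geno.expected
    m = gmap.n_loci
    lam = np.full(m, np.nan)
    gamma = np.zeros(m)
    gvar = np.full(m, np.nan)
    wald = np.zeros(m)
    pval = np.ones(m)
    n_degenerate = 0
    lambda0_report = np.nan
    sigma2_report = np.nan

    if kinship == "whole":
        key = ("whole",)
        if key not in eig_cache:
            K = build_kinship(geno)
            delta, U = linalg.eigh(K.matrix, check_finite=False, driver="evd")
            eig_cache[key] = (np.clip(delta, 0.0, None), U)
        delta, U = eig_cache[key]
        pg = fit_polygenic(y, X, np.empty(0), eig=(delta, U))
        lambda0_report, sigma2_report = pg.lambda_, pg.sigma2
        out = _scan_columns(y, X, Z, delta, U, pg.lambda_, effect)
        lam, gamma, gvar, wald, pval, n_degenerate = out
    else:
        # group scan loci by flanking true-marker pair; drop that pair from K
        lambda0s = []
        for chrom in gmap.chromosomes:
            idx = gmap.chrom_indices(chrom)
            true_idx = idx[~gmap.is_pseudo[idx]]
            true_pos = gmap.position[true_idx]
            mt = true_idx.size
            pos = gmap.position[idx]
            if mt < 2:
                interval = np.zeros(pos.size, dtype=int)
                pairs = [(gmap.name[true_idx[0]],)] if mt == 1 else [()]
            else:
                interval = np.clip(
                    np.searchsorted(true_pos, pos, side="right") - 1, 0, mt - 2
                )
                pairs = [
                    (gmap.name[true_idx[i]], gmap.name[true_idx[i + 1]])
                    for i in range(mt - 1)
                ]
            for g, pair in enumerate(pairs):
                sel = idx[interval == g]
                if sel.size == 0:
                    continue
                key = ("part", chrom, pair)
                if key not in eig_cache:
                    K = build_kinship(geno, exclude=pair)
                    d_, U_ = linalg.eigh(K.matrix, check_finite=False, driver="evd")
                    eig_cache[key] = (np.clip(d_, 0.0, None), U_)
                d_, U_ = eig_cache[key]
                pg = fit_polygenic(y, X, np.empty(0), eig=(d_, U_))
                lambda0s.append(pg.lambda_)
                res = _scan_columns(y, X, Z[:, sel], d_, U_, pg.lambda_, effect)
                lam[sel], gamma[sel], gvar[sel], wald[sel], pval[sel] = res[:5]
                n_degenerate += res[5]
        lambda0_report = float(np.median(lambda0s)) if lambda0s else np.nan

    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} scan loci were monomorphic or collinear with "
            "the fixed effects; their p-values are 1",
            stacklevel=2,
        )
    pval = np.clip(pval, P_FLOOR, 1.0)
    table = gmap.to_frame()
    table["lambda_k"] = lam
    table["effect"] = gamma
    table["gamma_var"] = gvar
    table["wald"] = wald
    table["p_value"] = pval
    table["neglog10p"] = -np.log10(pval)
    return ScanResult(
        table=table,
        lambda0=lambda0_report,
        sigma2_polygenic=sigma2_report,
        n_degenerate=n_degenerate,
    )


def select_peaks(scan: ScanResult) -> CandidateSet:
    """All local maxima of the -log10 p curve, per chromosome.

    A peak strictly exceeds its left neighbor and is >= its right neighbor
    (so a plateau contributes its leftmost point); chromosome ends are
    compared one-sided. Deliberately no p-value threshold: stage two sorts
    out which candidates are real.
    """
    if len(scan) == 0:
        raise ValueError("empty scan result")
    tab = scan.table
    v = tab["neglog10p"].to_numpy()
    chroms = tab["chromosome"].to_numpy()
    peaks = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        vc = v[idx]
        up = np.empty(idx.size, dtype=bool)
        up[0] = True
        up[1:] = vc[1:] > vc[:-1]
        down = np.empty(idx.size, dtype=bool)
        down[-1] = True
        down[:-1] = vc[:-1] >= vc[1:]
        peaks.extend(idx[up & down].tolist())
    peaks = np.asarray(sorted(peaks), dtype=int)
    return CandidateSet(indices=peaks, table=tab.iloc[peaks].reset_index(drop=True))
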