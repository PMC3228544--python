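"""Scoring of significance tests against simulated truth.

TPR is the proportion of causal SNPs declared significant at the nominal
threshold alpha, FPR the proportion of non-causal SNPs declared
significant; both are averaged over replicates as unweighted means of the
per-replicate proportions.  A non-causal SNP in perfect LD with the causal
SNP still counts as a false positive, and a causal SNP dropped as
invariant during preprocessing counts as not detected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import PenaltySpec, preprocess
from .exceptions import ValidationError
from .linear import LinearRidge
from .logistic import LogisticRidge
from .significance import approximate_test, permutation_test
from .simulate import HaplotypePanel, ScenarioConfig, simulate_replicate


@dataclass
class EvaluationSummary:
    """TPR/FPR per (test, lambda) for one scenario."""

    table: pd.DataFrame  # columns: test, lam, tpr, fpr
    replicates: int
    alpha: float
    scenario: ScenarioConfig

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "n", self.scenario.n)
        out.insert(1, "m", self.scenario.m)
        out.insert(2, "outcome", self.scenario.phenotype_kind)
        if self.scenario.effect_model == "null":
            out = out.drop(columns=["tpr"])
        return out


def tpr_fpr(p_values, causal_idx, alpha: float,
            n_causal_total: int | None = None) -> tuple[float, float]:
    """True/false positive proportions at threshold alpha.

    ``causal_idx`` indexes the causal SNPs among the tested p-values.
    ``n_causal_total`` (>= len(causal_idx)) counts causal SNPs that were
    designated but dropped before testing; they enter the TPR denominator
    as undetected.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    causal = np.asarray(causal_idx, dtype=int).ravel()
    if n_causal_total is None:
        n_causal_total = causal.size
    if n_causal_total < causal.size:
        raise ValidationError("n_causal_total smaller than the surviving causal count")
    if n_causal_total > causal.size:
        warnings.warn(
            f"{n_causal_total - causal.size} causal SNP(s) dropped before "
            "testing; counted as not detected", UserWarning, stacklevel=2,
        )
    is_causal = np.zeros(p.size, dtype=bool)
    is_causal[causal] = True
    sig = p < alpha
    tpr = float(sig[is_causal].sum() / n_causal_total) if n_causal_total else float("nan")
    n_null = int((~is_causal).sum())
    fpr = float(sig[~is_causal].mean()) if n_null else float("nan")
    return tpr, fpr


def rank_snps(p_values) -> np.ndarray:
    """Rank SNPs by p-value, 1 = most significant; ties share the minimum rank."""
    return rankdata(np.asarray(p_values, dtype=float), method="min").astype(int)


def bland_altman(p_approximate, p_permutation, B: int = 1000):
    """Per-SNP mean and difference of p-values on the -log10 scale.

    The difference is (permutation - approximate) on the -log10 scale; a
    negative mean difference therefore indicates smaller (more significant)
    p-values from the approximate test.  Exact zeros are floored at
    1/(10 B) before taking logs.
    """
    pa = np.asarray(p_approximate, dtype=float).ravel()
    pb = np.asarray(p_permutation, dtype=float).ravel()
    if pa.size != pb.size:
        raise ValidationError("p-value vectors must have equal length")
    floor = 1.0 / (10.0 * B)
    la = -np.log10(np.clip(pa, floor, None))
    lb = -np.log10(np.clip(pb, floor, None))
    return (la + lb) / 2.0, lb - la


# ----------------------------------------------------------------------
def run_scenario(panel: HaplotypePanel, config: ScenarioConfig,
                 tests: tuple[str, ...] = ("approximate",),
                 B: int = 1000, null_dist: str = "normal",
                 max_iter: int = 50) -> EvaluationSummary:
    """Simulate -> preprocess -> fit -> test -> score, per lambda and replicate.

    Returns the unweighted mean of per-replicate TPR/FPR for every
    (test, lambda) combination in the scenario's grid.
    """
    for t in tests:
        if t not in ("approximate", "permutation"):
            raise ValidationError(f"unknown test {t!r}")
    root = np.random.SeedSequence(config.seed)
    rep_seqs = root.spawn(config.replicates)
    rows: dict[tuple[str, float], list[tuple[float, float]]] = {
        (t, lam): [] for t in tests for lam in config.lam_grid
    }
    for rep, seq in enumerate(rep_seqs):
        G, y, causal_pos = simulate_replicate(panel, config, seq)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            Gp = preprocess(G)
        kept = {orig: new for new, orig in enumerate(Gp.source_index)}
        surv_causal = np.array([kept[c] for c in causal_pos if c in kept], dtype=int)
        n_causal_total = len(causal_pos)
        perm_seed_root = seq.spawn(1)[0]
        if config.phenotype_kind == "continuous":
            model = LinearRidge(y, Gp)
        for li, lam in enumerate(config.lam_grid):
            if config.phenotype_kind == "continuous":
                fit = model.fit(lam)
            else:
                fit = LogisticRidge(y, Gp).fit(lam, max_iter=max_iter)
            for t in tests:
                if t == "approximate":
                    p = approximate_test(fit, null_dist=null_dist).p_values
                else:
                    sub = int(perm_seed_root.spawn(1)[0].generate_state(1)[0] % (2**31))
                    p = permutation_test(
                        Gp, y, PenaltySpec(lam=lam),
                        model="linear" if config.phenotype_kind == "continuous" else "logistic",
                        B=B, seed=sub,
                    ).p_values
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    tpr, fpr = tpr_fpr(p, surv_causal, config.alpha,
                                       n_causal_total=n_causal_total)
                rows[(t, lam)].append((tpr, fpr))
    records = []
    for (t, lam), vals in rows.items():
        tprs = [v[0] for v in vals]
        fprs = [v[1] for v in vals]
        records.append({
            "test": t, "lam": lam,
            "tpr": float(np.nanmean(tprs)) if n_total_causal_nonzero(config) else float("nan"),
            "fpr": float(np.mean(fprs)),
        })
    table = pd.DataFrame(records).sort_values(["test", "lam"]).reset_index(drop=True)
    return EvaluationSummary(table=table, replicates=config.replicates,
                             alpha=config.alpha, scenario=config)


def n_total_causal_nonzero(config: ScenarioConfig) -> bool:
    return config.effect_model != "null"
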