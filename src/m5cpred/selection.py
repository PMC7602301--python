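"""Sequential forward selection (SFS) over feature families.

Greedy wrapper search scored by 10-fold cross-validated AUROC: round 1
evaluates each candidate family alone; every later round tries adding each
remaining family to the incumbent subset; the search stops when no addition
strictly improves the AUROC.  Hyper-parameters (C, kernel scale) are
re-searched for every candidate subset.  Ties prefer the lower-dimensional
subset (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .features import FamilyDescriptor, FeatureSpec
from .sequence_core import LabeledDataset
from .training import DEFAULT_SEED, CVResult, SVMGrid, cross_validate


@dataclass
class SFSRound:
    candidate: FeatureSpec
    result: CVResult
    chosen: bool

    @property
    def auroc(self) -> float:
        return self.result.auroc


@dataclass
class SFSTrace:
    rounds: list[SFSRound]
    final_subset: FeatureSpec
    final_auroc: float

    def n_evaluations(self) -> int:
        return len(self.rounds)

    def to_frame(self) -> pd.DataFrame:
        """One row per evaluated subset, mirroring a feature-selection
        report table (subset, KS, BC, Sn, Sp, Pre, Acc, Mcc, F1, AUC)."""
        rows = []
        for rnd in self.rounds:
            rep = rnd.result.mean_report()
            rows.append({
                "Feature subset": rnd.candidate.name,
                "KS": rnd.result.kernel_scale,
                "BC": rnd.result.box_constraint,
                "Sn (%)": 100 * rep.Sn,
                "Sp (%)": 100 * rep.Sp,
                "Pre (%)": 100 * rep.Pre,
                "Acc (%)": 100 * rep.Acc,
                "Mcc": rep.Mcc,
                "F1score": rep.F1,
                "AUC": rep.AUROC,
                "chosen": rnd.chosen,
            })
        return pd.DataFrame(rows)


def sequential_forward_selection(
    data: LabeledDataset,
    candidates: list[FamilyDescriptor],
    grid: SVMGrid,
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    ksnpf_denominator: str = "window",
) -> SFSTrace:
    """Greedy forward search over feature families by CV AUROC.

    Performs at most k(k+1)/2 cross-validated evaluations for k candidate
    families; with the same seed the trace is identical run to run.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate families")
    remaining = list(candidates)
    incumbent: FeatureSpec | None = None
    incumbent_auroc = float("-inf")
    rounds: list[SFSRound] = []

    while remaining:
        evaluated: list[SFSRound] = []
        for desc in remaining:
            spec = (
                FeatureSpec((desc,)) if incumbent is None
                else incumbent.with_family(desc)
            )
            res = cross_validate(
                data, spec, grid, folds=folds, seed=seed,
                ksnpf_denominator=ksnpf_denominator,
            )
            evaluated.append(SFSRound(candidate=spec, result=res, chosen=False))
        # best candidate of this round; ties prefer the lower-dimensional subset
        best = min(
            evaluated,
            key=lambda r: (-r.auroc, r.candidate.dim(data.lambda_flank)),
        )
        improved = best.auroc > incumbent_auroc
        if improved:
            best.chosen = True
        rounds.extend(evaluated)
        if not improved:
            break
        incumbent = best.candidate
        incumbent_auroc = best.auroc
        chosen_desc = incumbent.families[-1]
        remaining = [d for d in remaining if d.key != chosen_desc.key]

    assert incumbent is not None  # round 1 always improves over -inf
    return SFSTrace(rounds=rounds, final_subset=incumbent, final_auroc=incumbent_auroc)


def select_gap_k(
    data: LabeledDataset,
    family: str,
    k_grid: list[int],
    grid: SVMGrid,
    folds: int = 10,
    seed: int = DEFAULT_SEED,
) -> int:
    """Pick the gap K maximizing single-family CV AUROC (ties -> smaller K)."""
    if family not in ("KSNPF", "KSPSDP"):
        raise ValueError("family must be KSNPF or KSPSDP")
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    max_k = 2 * data.lambda_flank - 1
    for k in k_grid:
        if not 0 <= k <= max_k:
            raise ValueError(f"invalid K={k} for lambda={data.lambda_flank}")
    results = {}
    for k in k_grid:
        spec = FeatureSpec((FamilyDescriptor(family, K=k),))
        results[k] = cross_validate(data, spec, grid, folds=folds, seed=seed).auroc
    return min(results, key=lambda k: (-results[k], k))
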