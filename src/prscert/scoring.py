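"""Fixed-weight PRS scoring with allele alignment.

Scores individuals as the weighted sum of effect-allele dosages using an
externally supplied per-SNP weights table (PGS-Catalog scoring-file style:
rsID, effect allele, other allele, effect weight on the log-OR scale). No
interval accompanies the fixed-weight score. Alignment handles swapped
allele coding (sign flip with the complement-dosage offset, so scores are
invariant to which allele the genotype file counts) and flags
strand-ambiguous A/T and C/G variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class WeightSet:
    """External per-SNP weights: id, effect_allele, other_allele, weight."""

    table: pd.DataFrame
    label: str = "external"

    def __post_init__(self) -> None:
        required = {"id", "effect_allele", "other_allele", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"weights table lacks columns {sorted(missing)}")
        if self.table["id"].duplicated().any():
            raise ValueError("weight identifiers must be unique")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")
        self.table = self.table.reset_index(drop=True)


@dataclass
class AlignedWeights:
    """Weights matched to genotype columns, with flip bookkeeping.

    ``weight`` is applied to the genotype's counted-allele dosage directly;
    for flipped variants it is the negated external weight and ``offset``
    carries the ``2 x`` original-weight constant so that
    ``w_ext * (2 - dosage) = offset + weight * dosage`` exactly.
    """

    variant_index: np.ndarray  # column indices into the genotype matrix
    weight: np.ndarray
    offset: np.ndarray
    ids: list[str]
    label: str = "external"

    @property
    def n_variants(self) -> int:
        return len(self.ids)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in _AMBIGUOUS


def align_weights(
    weights: WeightSet,
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = False,
) -> tuple[AlignedWeights, pd.DataFrame]:
    """Match a weights table to genotype columns, flipping swapped alleles.

    Returns the aligned weights and a per-SNP report with status in
    ``{matched, flipped, ambiguous, ambiguous_dropped, allele_mismatch,
    missing}``. Variants whose genotype counted allele is the weights file's
    *other* allele get a negated weight plus a ``2 x weight`` offset, which
    leaves every individual's score identical to scoring the complementary
    dosage. Raises if no variant can be aligned.
    """
    indexer = genotypes.variant_indexer()
    gv = genotypes.variants
    rows = []
    idx, wts, offs, ids = [], [], [], []
    for rec in weights.table.itertuples(index=False):
        rid = rec.id
        w = float(rec.weight)
        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        j = indexer.get(rid)
        if j is None:
            rows.append((rid, "missing", np.nan))
            continue
        g_ea = gv.at[j, "effect_allele"].upper()
        g_oa = gv.at[j, "other_allele"].upper()
        ambiguous = _is_ambiguous(ea, oa)
        if ambiguous and drop_ambiguous:
            rows.append((rid, "ambiguous_dropped", np.nan))
            continue
        if (ea, oa) == (g_ea, g_oa):
            status = "ambiguous" if ambiguous else "matched"
            idx.append(j)
            wts.append(w)
            offs.append(0.0)
            ids.append(rid)
            rows.append((rid, status, w))
        elif (ea, oa) == (g_oa, g_ea):
            status = "ambiguous" if ambiguous else "flipped"
            idx.append(j)
            wts.append(-w)
            offs.append(2.0 * w)
            ids.append(rid)
            rows.append((rid, status, -w))
        else:
            rows.append((rid, "allele_mismatch", np.nan))

    report = pd.DataFrame(rows, columns=["id", "status", "aligned_weight"])
    if not ids:
        raise ValueError("no overlapping variants between weights and genotypes")
    aligned = AlignedWeights(
        variant_index=np.asarray(idx, dtype=int),
        weight=np.asarray(wts, dtype=float),
        offset=np.asarray(offs, dtype=float),
        ids=ids,
        label=weights.label,
    )
    return aligned, report


def score_fixed(
    genotypes: GenotypeMatrix,
    weights: AlignedWeights,
    standardize: bool = False,
) -> np.ndarray:
    """PRS_i = sum_j dosage_ij * w_j (+ flip offsets) over aligned variants.

    Missing dosages are imputed as twice the cohort effect-allele frequency
    (the PLINK scoring convention). With ``standardize`` the scores are
    cohort z-scored.
    """
    d = genotypes.dosages[:, weights.variant_index]
    if np.isnan(d).any():
        fill = 2.0 * (np.nanmean(d, axis=0) / 2.0)
        nan_idx = np.where(np.isnan(d))
        d = d.copy()
        d[nan_idx] = fill[nan_idx[1]]
    scores = d @ weights.weight + weights.offset.sum()
    if standardize:
        sd = scores.std(ddof=1)
        if sd == 0:
            raise ValueError("cannot standardize constant scores")
        scores = (scores - scores.mean()) / sd
    return scores
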