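"""Per-pair retrieval significance from the evaluation log.

The evaluation log records, for every test record, whether its (IDP, SNP)
pair was retrieved correctly in its batch.  Collating these gives per-pair
counts (n_correct, n_seen); each pair is then tested against the null that
every pair shares the model's overall retrieval accuracy, with a 2-cell
goodness-of-fit chi-square (df = 1):

    E_k   = n_seen_k * (sum n_correct / sum n_seen)
    chi2_k = (n_correct_k - E_k)^2 / E_k
           + ((n_seen_k - n_correct_k) - (n_seen_k - E_k))^2 / (n_seen_k - E_k)

Because frequencies differ wildly between strongly and weakly learned pairs,
a scaled statistic chi2 / N_obs is reported alongside (N_obs the total
observation count by default, the pair's own n_seen optionally), and
p-values are adjusted by Benjamini-Hochberg (Bonferroni optionally).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .io import PAIR_SCORE_COLUMNS


def collate_frequencies(eval_log: pd.DataFrame,
                        correct_col: str = "correct") -> pd.DataFrame:
    """Exact per-pair counts from the evaluation log.

    Returns one row per unique (idp_id, snp_id) with n_seen and n_correct;
    the n_seen column sums to the log length.
    """
    if eval_log.empty:
        raise ValueError("empty evaluation log")
    g = (eval_log.assign(_c=eval_log[correct_col].astype(int))
         .groupby(["idp_id", "snp_id"], sort=True)["_c"]
         .agg(n_seen="count", n_correct="sum")
         .reset_index())
    return g[["idp_id", "snp_id", "n_seen", "n_correct"]]


def score_pairs(freqs: pd.DataFrame, n_obs: int | None = None,
                correction: str = "global", adjust: str = "bh") -> pd.DataFrame:
    """Chi-square significance per pair against the uniform-accuracy null.

    Pairs with a degenerate null (expected counts of zero, i.e. overall
    accuracy 0 or 1) are flagged and assigned p = 1.
    """
    if correction not in ("global", "per_pair"):
        raise ValueError(f"unknown correction {correction!r}")
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    freqs = freqs.reset_index(drop=True)
    seen = freqs["n_seen"].to_numpy(float)
    correct = freqs["n_correct"].to_numpy(float)
    if (seen <= 0).any() or (correct < 0).any() or (correct > seen).any():
        raise ValueError("invalid frequency counts")
    if len(freqs) < 2:
        raise ValueError("need at least 2 pairs with observations")
    total_seen = seen.sum()
    acc = correct.sum() / total_seen
    expected = seen * acc
    miss_expected = seen - expected
    degenerate = (expected <= 0) | (miss_expected <= 0)
    chi2 = np.zeros(len(freqs))
    ok = ~degenerate
    chi2[ok] = ((correct[ok] - expected[ok]) ** 2 / expected[ok]
                + ((seen[ok] - correct[ok]) - miss_expected[ok]) ** 2 / miss_expected[ok])
    p = np.ones(len(freqs))
    p[ok] = chi2_dist.sf(chi2[ok], df=1)
    if n_obs is None:
        n_obs = int(total_seen)
    denom = seen if correction == "per_pair" else float(n_obs)
    chi2_corrected = chi2 / denom
    if adjust == "bh":
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        p_adj = np.minimum(p * len(p), 1.0)
    out = freqs.copy()
    out["chi2"] = chi2
    out["chi2_corrected"] = chi2_corrected
    out["p"] = p
    out["p_adj"] = p_adj
    out["degenerate"] = degenerate
    # the chi-square is two-sided; a "learned" pair deviates upward
    out["enriched"] = correct > expected
    out = out.sort_values(["p_adj", "p", "idp_id", "snp_id"],
                          kind="mergesort").reset_index(drop=True)
    return out[PAIR_SCORE_COLUMNS + ["degenerate", "enriched"]]


def score_eval_log(eval_log: pd.DataFrame, correct_col: str = "correct",
                   correction: str = "global", adjust: str = "bh") -> pd.DataFrame:
    """Convenience: collate an evaluation log and score its pairs."""
    return score_pairs(collate_frequencies(eval_log, correct_col),
                       correction=correction, adjust=adjust)
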