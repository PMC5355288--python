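"""Cross-dataset hub replication and two-sample power analysis.

Replication tests a small pre-specified hub set in an independent cohort two
ways: (A) significance read off the genome-wide FDR adjustment, and (B) the
same raw p-values re-adjusted over the hub subset only. Because the
restricted family is tiny, (B) routinely recovers genes that the
genome-wide correction drowns — that ordering is the point of pre-specifying
candidates. Power for the tumor-style comparison is the exact two-sided
two-sample t-test power via the noncentral t distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable, ExpressionMatrix, fit_de, restricted_test
from .interactome import GeneList
from .topology import HubSet

log = logging.getLogger(__name__)

__all__ = ["ReplicationReport", "PowerSpec", "replicate_hubs", "power_two_sample"]


@dataclass
class ReplicationReport:
    """Per-hub replication table.

    Columns: availability (measured / not_measured), logFC, p (identical
    under both adjustments), adj_p_whole (A: genome-wide family),
    adj_p_restricted (B: hub-only family), significance flags at ``fdr_q``,
    and direction concordance with the discovery dataset when discovery
    directions are supplied.
    """

    table: pd.DataFrame
    fdr_q: float
    de_full: DETable

    @property
    def measured(self) -> pd.DataFrame:
        return self.table[self.table["availability"] == "measured"]


def replicate_hubs(
    validation: ExpressionMatrix,
    hubs: HubSet | GeneList,
    fdr_q: float = 0.10,
    covariates: tuple[str, ...] = (),
    discovery_directions: dict[str, str] | None = None,
) -> ReplicationReport:
    """Assess hub differential expression in an independent validation cohort.

    Fits the genome-wide contrast on ``validation`` (with optional family /
    batch blocking covariates), then reports each hub under whole-list (A)
    and restricted-list (B) multiplicity adjustment. Hubs absent from the
    validation platform are flagged, with no statistics. Raises if no hub is
    measured at all.
    """
    hub_genes = GeneList(hubs.genes if isinstance(hubs, HubSet) else list(hubs), label="hubs")
    if len(hub_genes) == 0:
        raise ValueError("empty hub set")
    full = fit_de(validation, covariates=covariates, fdr_q=fdr_q)
    tested = set(full.table.index)
    if not (hub_genes.as_set & tested):
        raise ValueError("none of the hub genes are measured on the validation platform")
    restricted = restricted_test(full, hub_genes, fdr_q=fdr_q)
    rows = []
    for gene in hub_genes:
        if gene not in tested:
            rows.append(
                {
                    "gene": gene,
                    "availability": "not_measured",
                    "logFC": np.nan,
                    "p": np.nan,
                    "adj_p_whole": np.nan,
                    "adj_p_restricted": np.nan,
                    "sig_whole": False,
                    "sig_restricted": False,
                    "concordant": np.nan,
                }
            )
            continue
        logfc = full.table.at[gene, "logFC"]
        conc: object = np.nan
        if discovery_directions and gene in discovery_directions:
            conc = (logfc > 0) == (discovery_directions[gene] == "up")
        rows.append(
            {
                "gene": gene,
                "availability": "measured",
                "logFC": logfc,
                "p": full.table.at[gene, "p"],
                "adj_p_whole": full.table.at[gene, "adj_p"],
                "adj_p_restricted": restricted.table.at[gene, "adj_p"],
                "sig_whole": bool(full.table.at[gene, "adj_p"] <= fdr_q),
                "sig_restricted": bool(restricted.table.at[gene, "adj_p"] <= fdr_q),
                "concordant": conc,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    return ReplicationReport(table=table, fdr_q=fdr_q, de_full=full)


@dataclass
class PowerSpec:
    """Inputs and result of a two-sample t-test power computation.

    ``fold_change`` is on the ratio scale (its log2 is the mean difference),
    ``sd_log2`` the common per-group SD of log2 expression, and ``n_tests``
    the Bonferroni multiplicity applied to alpha when > 1.
    """

    n1: int
    n2: int
    fold_change: float
    sd_log2: float
    alpha: float = 0.05
    n_tests: int = 1
    power: float | None = None


def power_two_sample(spec: PowerSpec) -> PowerSpec:
    """Exact two-sided two-sample t-test power.

    Noncentrality ncp = log2(fold_change) / (sd_log2 * sqrt(1/n1 + 1/n2)),
    df = n1 + n2 - 2; power is the probability mass of the noncentral t
    outside the central-t critical values at alpha (Bonferroni alpha/n_tests
    when n_tests > 1). At fold_change = 1 power equals the adjusted alpha.
    """
    if spec.sd_log2 <= 0:
        raise ValueError("sd_log2 must be positive")
    if not (0 < spec.alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if spec.n1 < 2 or spec.n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    alpha = spec.alpha / spec.n_tests if spec.n_tests > 1 else spec.alpha
    df = spec.n1 + spec.n2 - 2
    ncp = np.log2(spec.fold_change) / (spec.sd_log2 * np.sqrt(1 / spec.n1 + 1 / spec.n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    return replace(spec, power=power)
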