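"""Risk-gene definition: DE genes that are validated targets of DE miRNAs.

A gene is a risk gene when it is differentially expressed AND appears as
the validated target of at least one differentially expressed miRNA; the
(miRNA, gene) pairing is retained.  No direction-of-regulation filter is
applied — up-regulated genes may pair with up-regulated miRNAs.
"""

from __future__ import annotations

from typing import Iterable

from .types import MiRNATargetTable, RiskGeneResult


def map_risk_genes(
    de_mirnas: Iterable[str],
    de_genes: Iterable[str],
    targets: MiRNATargetTable,
) -> RiskGeneResult:
    """Intersect validated targets of DE miRNAs with DE genes.

    Returns the deduplicated (DE miRNA, risk gene) pairs together with
    provenance counts: how many DE miRNAs had any validated target and how
    many distinct genes those miRNAs target (before the DE-gene filter).
    """
    de_mirna_set = set(de_mirnas)
    de_gene_set = set(de_genes)
    tab = targets.table
    of_de_mirnas = tab[tab["mirna"].isin(de_mirna_set)]
    pairs = sorted(
        {
            (m, g)
            for m, g in zip(of_de_mirnas["mirna"], of_de_mirnas["target"])
            if g in de_gene_set
        }
    )
    return RiskGeneResult(
        pairs=pairs,
        n_de_mirnas_with_targets=of_de_mirnas["mirna"].nunique(),
        n_targets_of_de_mirnas=of_de_mirnas["target"].nunique(),
    )
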