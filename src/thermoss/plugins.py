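"""Adapters producing plug-in DE tables from external count-model packages.

The canonical DEG route of this pipeline is a plug-in table of per-contrast
log2 fold changes and p-values from a count-model DE analysis (the route the
original study took); the internal Welch and permutation tests are
self-contained stand-ins. This module generates such a table with pydeseq2
when it is installed; the import is deferred so the core package does not
depend on it.
"""

from __future__ import annotations

import contextlib
import io
import warnings

import pandas as pd

from .expression import CONTRASTS, ExpressionMatrix


def deseq2_de_table(counts: ExpressionMatrix) -> pd.DataFrame:
    """Wald-test DE table (gene_id, contrast, log2fc, pvalue) for every
    stress stage against H0, computed with pydeseq2 on raw counts."""
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    if counts.kind != "counts":
        raise ValueError("deseq2_de_table expects raw counts")
    meta = pd.DataFrame(
        {"stage": [s.stage for s in counts.samples]},
        index=[s.sample_id for s in counts.samples],
    )
    frames = []
    with warnings.catch_warnings(), contextlib.redirect_stdout(io.StringIO()):
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=counts.values.T, metadata=meta,
                           design="~stage", quiet=True)
        dds.deseq2()
        for contrast in CONTRASTS:
            stage = contrast.split("vs")[0]
            stats = DeseqStats(dds, contrast=["stage", stage, "H0"], quiet=True)
            stats.summary()
            df = stats.results_df
            frames.append(pd.DataFrame({
                "gene_id": df.index,
                "contrast": contrast,
                "log2fc": df["log2FoldChange"].to_numpy(),
                "pvalue": df["pvalue"].fillna(1.0).to_numpy(),
            }))
    return pd.concat(frames, ignore_index=True)
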