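"""Published cross-validation benchmark AUCs on the HMDD v2.0 corpus.

These are the reference constants against which relative improvement
(growth rate) is computed.  Reproducing them requires the external HMDD
v2.0 / MISIM / MeSH downloads, so they are shipped as constants, not
recomputed; ``None`` marks a protocol a method does not support.
"""

from __future__ import annotations

from .evaluate import growth_rate

__all__ = ["LOOCV_AUCS", "FIVE_FOLD_AUCS", "growth_table"]

#: global and local LOOCV AUCs reported for each method on HMDD v2.0
LOOCV_AUCS: dict[str, dict[str, float | None]] = {
    "SSCMDA": {"global": 0.9007, "local": 0.8747},
    "HGIMDA": {"global": 0.8781, "local": 0.8077},
    "RLSMDA": {"global": 0.8426, "local": 0.6953},
    "HDMP": {"global": 0.8366, "local": 0.7702},
    "WBSMDA": {"global": 0.8030, "local": 0.8031},
    "RWRMDA": {"global": None, "local": 0.7891},
    "MCMDA": {"global": 0.8749, "local": 0.7718},
}

#: mean +/- std AUC over 100 repetitions of 5-fold cross-validation
FIVE_FOLD_AUCS: dict[str, tuple[float, float]] = {
    "SSCMDA": (0.8806, 0.0025),
    "MCMDA": (0.8767, 0.0011),
    "RLSMDA": (0.8569, 0.0020),
    "HDMP": (0.8342, 0.0010),
    "WBSMDA": (0.8185, 0.0009),
}


def growth_table(reference: str = "SSCMDA") -> dict[str, dict[str, float | None]]:
    """Growth rate (%) of the reference method over every other method.

    Computed from the published AUC columns with :func:`~sscmda.evaluate.growth_rate`
    (half-up rounding to two decimals).
    """
    ref = LOOCV_AUCS[reference]
    table: dict[str, dict[str, float | None]] = {}
    for method, aucs in LOOCV_AUCS.items():
        if method == reference:
            continue
        row: dict[str, float | None] = {}
        for protocol in ("global", "local"):
            old = aucs[protocol]
            row[protocol] = None if old is None else growth_rate(ref[protocol], old)
        table[method] = row
    return table
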