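"""Reference tables bundled with the package.

The breast-carcinoma heterogeneity panel below was transcribed from a published
immunohistochemistry survey of resected breast cancers (roughly ten cases per
molecular subtype) scored for intra-tumoural staining heterogeneity across 14
metabolic and mTOR-pathway markers.  For each marker the table records, per
subtype, the number of heterogeneously stained cases over the number of
evaluable cases, together with the pooled heterogeneity percentage printed in
the source table.  A handful of printed percentages are not reproducible from
their own counts; :func:`tmshet.heterogeneity.audit_reference_table` flags
them rather than forcing agreement.
"""

from __future__ import annotations

import pandas as pd

SUBTYPES = ("LumA", "LumB", "HER2+", "TNBC")

#: marker -> ({subtype: (n_heterogeneous, n_evaluated)}, printed pooled percent)
BREAST_PANEL_HETEROGENEITY = {
    "Rictor": ({"LumA": (7, 9), "LumB": (5, 9), "HER2+": (6, 8), "TNBC": (3, 7)}, 60),
    "p-S6":   ({"LumA": (8, 9), "LumB": (8, 10), "HER2+": (8, 8), "TNBC": (8, 10)}, 87),
    "p-mTOR": ({"LumA": (9, 10), "LumB": (10, 10), "HER2+": (7, 9), "TNBC": (6, 10)}, 84),
    "GLUT1":  ({"LumA": (4, 10), "LumB": (6, 10), "HER2+": (9, 9), "TNBC": (7, 10)}, 67),
    "LDHA":   ({"LumA": (2, 10), "LumB": (4, 10), "HER2+": (3, 9), "TNBC": (2, 10)}, 28),
    "HK2":    ({"LumA": (6, 9), "LumB": (9, 10), "HER2+": (7, 8), "TNBC": (6, 10)}, 76),
    "PFKP":   ({"LumA": (2, 9), "LumB": (4, 10), "HER2+": (6, 8), "TNBC": (5, 8)}, 49),
    "ASCT2":  ({"LumA": (8, 10), "LumB": (10, 10), "HER2+": (8, 8), "TNBC": (9, 10)}, 92),
    "GLS":    ({"LumA": (1, 7), "LumB": (2, 9), "HER2+": (3, 7), "TNBC": (4, 8)}, 32),
    "FASN":   ({"LumA": (4, 10), "LumB": (6, 10), "HER2+": (5, 9), "TNBC": (4, 9)}, 45),
    "CPT1A":  ({"LumA": (6, 9), "LumB": (1, 10), "HER2+": (5, 9), "TNBC": (4, 9)}, 43),
    "ACC":    ({"LumA": (4, 8), "LumB": (6, 10), "HER2+": (6, 6), "TNBC": (3, 8)}, 59),
    "ACSS2":  ({"LumA": (2, 10), "LumB": (1, 10), "HER2+": (4, 9), "TNBC": (2, 10)}, 23),
    "ATPb":   ({"LumA": (0, 8), "LumB": (1, 8), "HER2+": (3, 7), "TNBC": (1, 8)}, 16),
}


def reference_heterogeneity_counts() -> pd.DataFrame:
    """Return the reference panel as a tidy DataFrame.

    Columns: ``marker, subtype, n_heterogeneous, n_evaluated, printed_percent``.
    """
    rows = []
    for marker, (per_subtype, printed) in BREAST_PANEL_HETEROGENEITY.items():
        for subtype, (k, n) in per_subtype.items():
            rows.append(
                {
                    "marker": marker,
                    "subtype": subtype,
                    "n_heterogeneous": k,
                    "n_evaluated": n,
                    "printed_percent": printed,
                }
            )
    return pd.DataFrame(rows)


def marker_prevalence() -> dict[str, float]:
    """Pooled heterogeneity prevalence per marker (Σhet/Σeval), as fractions.

    These serve as the default per-marker prevalence of the synthetic cohort
    generator, so simulated cohorts share the empirical marker-level spread
    (from ~0.16 for ATPb up to ~0.92 for ASCT2).
    """
    out = {}
    for marker, (per_subtype, _printed) in BREAST_PANEL_HETEROGENEITY.items():
        k = sum(v[0] for v in per_subtype.values())
        n = sum(v[1] for v in per_subtype.values())
        out[marker] = k / n
    return out
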