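"""Small shared helpers."""

from __future__ import annotations

__all__ = ["percent_positive"]


def percent_positive(n_positive: int, n_total: int, ndigits: int = 1) -> float:
    """Percentage of positive counts, rounded to ``ndigits`` decimals.

    Used for cell-count summaries such as the fraction of labeled cells
    immunopositive for a marker.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    return round(100.0 * n_positive / n_total, ndigits)
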