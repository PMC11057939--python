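"""GC content, CpG counts and observed/expected CpG ratios over nine windows.

The observed/expected ratio follows the Gardiner-Garden & Frommer convention:

    obs/exp = N_CpG * L / (N_C * N_G)

with L the N-free window length. N bases are excluded from both numerator
and denominator; a window with no C or no G has an undefined ratio (missing).
Statistics are computed on the wild-type window only: one substitution is
negligible at these window scales and the alt identity is carried by the
other feature groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from snvfeat.core import MISSING, FeatureBlock, VariantRecord
from snvfeat.sequence import ReferenceGenome, fetch_context

#: default flank widths (bp), spanning local context to CpG-island scale
DEFAULT_WINDOW_SIZES = [50, 100, 200, 300, 400, 500, 1000, 2500, 5000]


@dataclass
class GcCpgConfig:
    window_sizes: list[int] = field(default_factory=lambda: list(DEFAULT_WINDOW_SIZES))

    def __post_init__(self) -> None:
        ws = self.window_sizes
        if any(b <= a for a, b in zip(ws, ws[1:])):
            raise ValueError("window sizes must be strictly increasing")


def gc_content(s: str):
    """(#G + #C) / N-free length; missing for an all-N window."""
    if not s:
        raise ValueError("empty sequence")
    s = s.upper()
    denom = len(s) - s.count("N")
    if denom == 0:
        return MISSING
    return (s.count("G") + s.count("C")) / denom


def cpg_stats(s: str):
    """(CpG count, observed/expected ratio); ratio missing if no C or no G."""
    if not s:
        raise ValueError("empty sequence")
    s = s.upper()
    count = sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG")
    n_c, n_g = s.count("C"), s.count("G")
    length = len(s) - s.count("N")
    if n_c == 0 or n_g == 0:
        return count, MISSING
    return count, count * length / (n_c * n_g)


def gc_cpg_block(
    genome: ReferenceGenome, variant: VariantRecord, config: GcCpgConfig | None = None
) -> FeatureBlock:
    """Columns ``gc_w{w}``, ``cpg_count_w{w}``, ``cpg_obs_exp_w{w}`` per window.

    Windows are clamped at contig edges; statistics are then computed on the
    clamped wild-type window.
    """
    config = config or GcCpgConfig()
    values: dict[str, object] = {}
    for w in config.window_sizes:
        ctx = fetch_context(genome, variant, flank=w, clamp=True)
        count, obs_exp = cpg_stats(ctx.wt_seq)
        values[f"gc_w{w}"] = gc_content(ctx.wt_seq)
        values[f"cpg_count_w{w}"] = count
        values[f"cpg_obs_exp_w{w}"] = obs_exp
    return FeatureBlock(variant_key=variant.key, values=values)
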