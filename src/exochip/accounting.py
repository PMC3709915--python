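"""Variant- and pair-accounting arithmetic for the evaluation design.

Encodes the bookkeeping that turns a chip's full variant manifest into the
sets actually analyzed: removing laboratory-QC failures and duplicates for
frequency work, and removing sequence-unavailable and best-practices
failures for the concordance comparison. Defaults hold the published
HumanExome v1.0 joint-calling accounting and are fully overridable.
"""
from __future__ import annotations

from dataclasses import dataclass

from .concord import round_half_up


@dataclass(frozen=True)
class ChipAccounting:
    """Counts flowing through the evaluation design of a joint-called chip."""

    total_variants: int = 247_870
    qc_excluded: int = 8_994
    duplicate_variants: int = 811
    not_in_sequence: int = 56_042
    best_practices_in_comparison: int = 6_709
    comparison_samples: int = 530

    @property
    def passing_variants(self) -> int:
        """Variants surviving laboratory QC."""
        return self.total_variants - self.qc_excluded

    @property
    def snp_pass_rate_pct(self) -> float:
        """Passing variants as a percentage of the manifest, 1 decimal."""
        return round_half_up(100.0 * self.passing_variants / self.total_variants, 1)

    @property
    def frequency_variants(self) -> int:
        """Variants used for allele-frequency work (QC failures and
        duplicates removed)."""
        return self.total_variants - self.qc_excluded - self.duplicate_variants

    @property
    def comparison_variants(self) -> int:
        """Variants available for the sequence-concordance comparison."""
        return (
            self.total_variants - self.not_in_sequence - self.best_practices_in_comparison
        )

    @property
    def comparison_pairs(self) -> int:
        """Genotype pairs tested: comparison variants x comparison samples."""
        return self.comparison_variants * self.comparison_samples
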