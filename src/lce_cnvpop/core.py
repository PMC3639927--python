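"""Shared record types, genotype vocabularies and error classes."""

from __future__ import annotations

from dataclasses import dataclass

# Closed genotype vocabularies.  The deletion locus uses "+" for the intact
# allele and "-" for the deleted allele; the SNP is biallelic A/G.
CNV_HOM_REF = "+/+"
CNV_HET = "+/-"
CNV_HOM_ALT = "-/-"
CNV_GENOTYPES = (CNV_HOM_REF, CNV_HET, CNV_HOM_ALT)

SNP_HOM_REF = "AA"
SNP_HET = "AG"
SNP_HOM_ALT = "GG"
SNP_GENOTYPES = (SNP_HOM_REF, SNP_HET, SNP_HOM_ALT)

MISSING = "NA"

LOSS = "loss"
GAIN = "gain"


class LcePopError(Exception):
    """Base class for package errors."""


class ParseError(LcePopError):
    """Malformed on-disk input.  Carries file path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(LcePopError):
    """In-memory data violates a documented invariant."""


class ConfigError(LcePopError):
    """Invalid run configuration or simulation parameters."""


class PipelineError(LcePopError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass(frozen=True)
class CNVRegion:
    """A called (or ground-truth) copy-number region.

    Coordinates are 0-based half-open.  ``direction`` is ``loss`` or ``gain``
    and must agree with the sign of ``mean_log2``; ``caller`` records
    provenance (``rule``, ``window``, ``consensus`` or ``truth``).
    """

    chrom: str
    start: int
    end: int
    direction: str
    n_probes: int
    mean_log2: float
    caller: str
    comparison_id: str = ""

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end}: end - start < 1"
            )
        if self.direction not in (LOSS, GAIN):
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.n_probes < 1:
            raise ValidationError("n_probes must be >= 1")
        if self.mean_log2 < 0 and self.direction == GAIN:
            raise ValidationError("direction gain inconsistent with negative mean_log2")
        if self.mean_log2 > 0 and self.direction == LOSS:
            raise ValidationError("direction loss inconsistent with positive mean_log2")

    @property
    def span(self) -> int:
        return self.end - self.start


def overlap_bp(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(end_a, end_b) - max(start_a, start_b))
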