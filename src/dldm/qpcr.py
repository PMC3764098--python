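"""qPCR arithmetic for MSP percent methylation and IP enrichment.

Methylation-sensitive restriction PCR (MSP): genomic DNA is digested with
BfuCI, which destroys templates whose GATC sites are unmethylated; the
surviving signal relative to undigested input, normalized by the same ratio
at a GATC-free control amplicon (correcting loading and primer efficiency),
is the percent of methylated templates.

MeDIP/ChIP enrichment: the IP/input ratio of a region, normalized by the
IP/input ratio of an unmethylated reference locus (the *am* locus) to
correct primer-efficiency bias, and optionally rescaled per region to a
reference sample so that sample becomes 1 everywhere.

All ratios come from the exponential amplification law: a template at
relative quantity q crosses threshold at Ct = -log_E(q) cycles relative to
the reference, so RQ(a vs b) = E^(Ct_b - Ct_a). Amplification efficiency E
defaults to 2.0 (perfect doubling) and is configurable per assay.
Technical replicates are averaged on the Ct scale, i.e. a geometric mean on
the quantity scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "QpcrWell",
    "MspResult",
    "EnrichmentResult",
    "relative_quantity",
    "mean_ct",
    "msp_percent",
    "relative_enrichment",
    "normalize_to_reference_sample",
]

logger = logging.getLogger(__name__)

INPUT = "input"
DIGESTED_BFUCI = "digested_BfuCI"
DIGESTED_DPNII = "digested_DpnII"
IP = "IP"


@dataclass(frozen=True)
class QpcrWell:
    target_region: str
    condition: str  # input / digested_BfuCI / digested_DpnII / IP
    ct: float
    efficiency: float = 2.0
    sample: str = ""

    def __post_init__(self) -> None:
        if self.efficiency <= 1:
            raise ValueError(
                f"amplification efficiency must exceed 1, got {self.efficiency}"
            )


@dataclass
class MspResult:
    region: str
    percent_methylation: float  # in [0, 100] after clamping
    control_pair: str
    clamped: bool = False


@dataclass
class EnrichmentResult:
    region: str
    ratio_ip_over_input: float
    normalized_ratio: float
    normalizer: str


def relative_quantity(ct_a: float, ct_b: float, efficiency: float = 2.0) -> float:
    """Quantity of template a relative to template b: E^(ct_b - ct_a)."""
    if efficiency <= 1:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    return efficiency ** (ct_b - ct_a)


def mean_ct(cts: Sequence[float]) -> float:
    """Technical replicates averaged on the Ct scale (geometric mean of
    quantities)."""
    if not cts:
        raise ValueError("no Ct values")
    return sum(cts) / len(cts)


def _pick_ct(wells: Sequence[QpcrWell], region: str, condition: str) -> float:
    cts = [w.ct for w in wells if w.target_region == region and w.condition == condition]
    if not cts:
        raise ValueError(f"missing qPCR well: region={region!r} condition={condition!r}")
    return mean_ct(cts)


def msp_percent(
    wells: Sequence[QpcrWell],
    region: str,
    control_region: str,
    efficiency: float = 2.0,
    digested_condition: str = DIGESTED_BFUCI,
) -> MspResult:
    """Percent methylation of a region from digested/input well pairs.

    percent = 100 * RQ_region(digested vs input) / RQ_control(digested vs
    input), where the control pair targets a GATC-free amplicon and cancels
    loading and primer-efficiency differences. Values marginally above 100
    (full protection plus Ct noise) are clamped to 100 and flagged, never
    silently.
    """
    rq_region = relative_quantity(
        _pick_ct(wells, region, digested_condition),
        _pick_ct(wells, region, INPUT),
        efficiency,
    )
    rq_control = relative_quantity(
        _pick_ct(wells, control_region, digested_condition),
        _pick_ct(wells, control_region, INPUT),
        efficiency,
    )
    percent = 100.0 * rq_region / rq_control
    clamped = percent > 100.0
    if clamped:
        logger.warning(
            "MSP percent for %s is %.3f%% > 100%%; clamping to 100", region, percent
        )
        percent = 100.0
    return MspResult(
        region=region,
        percent_methylation=percent,
        control_pair=control_region,
        clamped=clamped,
    )


def relative_enrichment(
    wells: Sequence[QpcrWell],
    region: str,
    normalizer_region: str = "am",
    efficiency: float = 2.0,
) -> EnrichmentResult:
    """IP/input enrichment of a region, normalized to the *am*-locus pair.

    ratio = E^(Ct_input - Ct_IP) for the region; normalized ratio divides by
    the same quantity at the unmethylated reference locus, whose own
    enrichment is thereby set to 1.
    """
    ratio = relative_quantity(
        _pick_ct(wells, region, IP), _pick_ct(wells, region, INPUT), efficiency
    )
    ratio_norm = relative_quantity(
        _pick_ct(wells, normalizer_region, IP),
        _pick_ct(wells, normalizer_region, INPUT),
        efficiency,
    )
    return EnrichmentResult(
        region=region,
        ratio_ip_over_input=ratio,
        normalized_ratio=ratio / ratio_norm,
        normalizer=normalizer_region,
    )


def normalize_to_reference_sample(
    enrichments: pd.DataFrame, reference_sample: str
) -> pd.DataFrame:
    """Rescale per-region enrichment values to a reference sample.

    ``enrichments`` has columns (sample, region, value); every sample's
    value for a region is divided by the reference sample's value for that
    region, so the reference becomes 1 everywhere. Regions where the
    reference value is zero or missing come back NaN and are logged.
    """
    required = {"sample", "region", "value"}
    if not required.issubset(enrichments.columns):
        raise ValueError(f"enrichments must have columns {sorted(required)}")
    ref = enrichments.loc[enrichments["sample"] == reference_sample]
    if ref.empty:
        raise ValueError(f"reference sample {reference_sample!r} not present")
    ref_by_region: Mapping[str, float] = dict(zip(ref["region"], ref["value"]))
    out = enrichments.copy()
    normalized = []
    for _, row in out.iterrows():
        ref_val = ref_by_region.get(row["region"])
        if ref_val is None or ref_val == 0 or not math.isfinite(ref_val):
            logger.warning(
                "no usable reference value for region %r; normalized value is NaN",
                row["region"],
            )
            normalized.append(math.nan)
        else:
            normalized.append(row["value"] / ref_val)
    out["normalized"] = normalized
    return out
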