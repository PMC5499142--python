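#!/usr/bin/env python
"""Apply the marker-filter cascades to the simulated cross and panel VCFs.

Cross markers: >=10 per genotype class, <=30% of samples under Phred 15
(recoded missing), then samples missing >50% of sites excluded.  Panel
markers: >=20 per class, exact HWE p >= 1e-3, >=70% of genotypes at Phred
>= 15, then redundant same-scaffold profiles pruned to >=8 differences.
"""

from pathlib import Path

from scafmap.markerqc import (
    exclude_high_missing_samples,
    filter_cross_markers,
    filter_ld_markers,
    prune_redundant,
)
from scafmap.matrix import read_vcf, write_vcf

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cross = read_vcf(OUT / "cross.vcf")
    kept = filter_cross_markers(cross)
    kept, excluded = exclude_high_missing_samples(kept)
    print(
        f"cross: {cross.n_markers} -> {kept.n_markers} markers; "
        f"excluded {len(excluded)} high-missing offspring {excluded}, "
        f"{kept.n_samples} remain"
    )
    write_vcf(kept, OUT / "cross.filtered.vcf")

    panel = read_vcf(OUT / "panel.vcf")
    ld = filter_ld_markers(panel, mode="capture")
    pruned = prune_redundant(ld)
    print(
        f"panel: {panel.n_markers} -> {ld.n_markers} after quality/HWE/class "
        f"filters -> {pruned.n_markers} after redundancy pruning"
    )
    write_vcf(pruned, OUT / "panel.filtered.vcf")


if __name__ == "__main__":
    main()
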