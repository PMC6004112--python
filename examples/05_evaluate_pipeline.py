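"""Score a pipeline run against the known community composition.

Detection ratio (which expected taxa got reads), Pearson correlation of
counts vs. biomass, and the species-pair count-ratio report used to gauge
amplification bias.
"""

import pandas as pd

from hsta import (
    biomass_correlation,
    detection_ratio,
    load_expected_community,
    pair_ratio_report,
)

community = load_expected_community()  # 11 order/class taxa, 7 carabid species

# an abundance table as the classifier would emit it (counts per taxon)
abundance = pd.DataFrame(
    [
        ("Coleoptera", "order", "MPE5", "5p", 410),
        ("Diptera", "order", "MPE5", "5p", 75),
        ("Orthoptera", "order", "MPE5", "5p", 41),
        ("Blattodea", "order", "MPE5", "5p", 19),
        ("Isopoda", "order", "MPE5", "5p", 12),
        ("Arachnida", "order", "MPE5", "5p", 10),
        ("Scorpiones", "order", "MPE5", "5p", 11),
        ("CC1", "species", "MPE5", "5p", 23135),
        ("LL1", "species", "MPE5", "5p", 100),
        ("CC1", "species", "MPE5", "3p", 10355),
        ("LL1", "species", "MPE5", "3p", 100),
    ],
    columns=["taxon", "rank", "sample", "strand", "count"],
)

ratio, found, missing = detection_ratio(abundance, community, "order")
print(f"detection ratio: {ratio:.3f} ({len(found)} of {len(found) + len(missing)} orders)")
print("missed:", ", ".join(missing))

r = biomass_correlation(abundance, community, "order")
print(f"biomass correlation (counts vs. grams): r = {r:.3f}")

rep = pair_ratio_report(abundance, "CC1", "LL1")
print(f"CC1/LL1 count ratio: 5' {rep.ratio_5p:.2f}, 3' {rep.ratio_3p:.2f}, "
      f"mean {rep.mean_ratio:.2f}")
# With a biomass ratio near 56, a count ratio well above it indicates the
# heavier species was additionally favored by amplification.
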