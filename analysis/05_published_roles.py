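#!/usr/bin/env python
"""Push the published role tables through the role-intersection logic.

The transcribed common-network hub and bottleneck lists intersect to the
hub-bottleneck set; their union is the key gene set used as the enrichment
query; every key gene is checked against the cross-network shared hub and
bottleneck lists.  Writes results/published_roles.json.
"""

import argparse
import json
from pathlib import Path

from comorbnet import network as net
from comorbnet import published


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/published_roles.json"))
    args = parser.parse_args()

    call = net.roles_from_lists(published.common_hub_set(), published.common_bottleneck_set())
    key = net.key_genes(call, published.shared_hub_set(), published.shared_bottleneck_set())
    terms = published.reported_enrichment()

    out = {
        "common_hubs": sorted(call.hubs),
        "common_bottlenecks": sorted(call.bottlenecks),
        "hub_bottlenecks": sorted(call.hub_bottlenecks),
        "key_genes": sorted(key.index),
        "all_key_genes_among_shared_hubs": bool(key["in_shared_hubs"].all()),
        "n_shared_hubs": len(published.shared_hub_set()),
        "n_shared_bottlenecks": len(published.shared_bottleneck_set()),
        "reported_term_rows": int(len(terms)),
        "reported_distinct_terms": int(terms["term"].nunique()),
        "reported_term_groups": sorted(set(terms["group"]) - {""}),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
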