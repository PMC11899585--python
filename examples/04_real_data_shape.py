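"""Round-trip a study through the on-disk format used for real data.

Writes a small synthetic study as the three tables a real analysis needs
(feature table, phenotype table, feature-to-network map), builds a network
map from a taxonomy the way a microbiome study would (top phyla by OTU
count, remainder pooled as "other"), and reads everything back.
"""

import tempfile
from pathlib import Path

import pandas as pd

import medcnn
from medcnn.io import build_network_map, read_dataset, write_dataset

config = medcnn.make_scenario("alternative", n=60, network_sizes=(6, 5, 4),
                              seed=2)
data = medcnn.generate_dataset(config)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_dataset(data, Path(tmp))
    print("wrote:", *[p.name for p in paths.values()])
    back = read_dataset(paths["features"], paths["phenotype"],
                        paths["network_map"])
    print(f"read back: n={back.n}, networks={back.network_labels}, "
          f"sizes={back.network_sizes}")

# building a network map from a phylum assignment table
taxonomy = pd.DataFrame({
    "feature_id": [f"OTU{i}" for i in range(10)],
    "phylum": ["Firmicutes"] * 4 + ["Proteobacteria"] * 3
              + ["Actinobacteria"] * 2 + ["Fusobacteria"],
})
nm = build_network_map(taxonomy, top_k=3)
print("networks from taxonomy:", nm.networks)
print("OTU9 ->", nm.assignment["OTU9"], "(minor phylum pooled into 'other')")
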