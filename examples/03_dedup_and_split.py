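"""Deduplicate chains by global-alignment identity and split by quality bin.

Two of the four chains below share > 70% sequence identity, so one is
dropped; the retained records are then partitioned train/validation/test
with bin stratification.
"""

from cryosse import deduplicate, nw_identity
from cryosse.curation import QualityRecord, stratified_split
from cryosse.io_formats import AtomicChain, Residue

def chain(seq, cid):
    return AtomicChain(
        cid, [Residue(i + 1, aa, [3.8 * i, 0, 0]) for i, aa in enumerate(seq)]
    )

chains = [
    chain("ACDEFGHIKLMNPQRSTVWY", "A"),
    chain("ACDEFGHIKLMNPQRSTVWA", "B"),  # 95% identical to A
    chain("WYWYWYWYWYWYWYWYWYWY", "C"),
    chain("MNPQRSTVWYACDEFGHIKL", "D"),
]
print("identity A-B:", round(nw_identity(chains[0].sequence, chains[1].sequence), 2))
kept = deduplicate(chains, threshold=0.70)
print("retained after dedup:", [c.chain_id for c in kept])

records = [
    QualityRecord(f"bin{b}_{i}", 0.7, 0.7, {1: 0.8, 2: 0.65, 3: 0.57}[b], 0.05, b)
    for b in (1, 2, 3)
    for i in range(10)
]
split = stratified_split(records, fractions=(0.8, 0.1, 0.1), seed=0)
for subset in ("train", "validation", "test"):
    print(subset, len(split.keys_for(subset)), "chains")
# Each bin contributes proportionally to every subset, so no subset is
# dominated by one quality stratum.
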