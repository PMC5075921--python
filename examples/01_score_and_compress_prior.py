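"""Score literature endorsements into edge confidences and compress.

Builds a tiny prior knowledge network from publication endorsement counts,
then removes the unidentifiable pass-through protein, keeping the
bottleneck confidence along the merged cascade.
"""

import fuzzysig as fs
from fuzzysig.prior import compress_network

records = [
    # EGF -> RAS seen in 2 low-throughput studies
    fs.EndorsementRecord("EGF", "RAS", +1, n_low=2),
    # RAS -> ERK seen in 1 low-throughput and 2 high-throughput studies
    fs.EndorsementRecord("RAS", "ERK", +1, n_low=1, n_high=2),
    # ERK -| apoptosis seen only in 1 high-throughput screen
    fs.EndorsementRecord("ERK", "APO", -1, n_high=1),
]
roles = {"EGF": "stimulated", "ERK": "measured", "APO": "measured",
         "RAS": "undesignated"}

prior = fs.build_prior(records, roles)
print("scored edges:")
for e in prior.edges:
    print(f"  {e.source} {'->' if e.sign == 1 else '-|'} {e.target}"
          f"  w = {e.confidence:.2f}")

compressed = compress_network(prior)
print("after compressing the undesignated RAS node:")
for e in compressed.edges:
    print(f"  {e.source} {'->' if e.sign == 1 else '-|'} {e.target}"
          f"  w = {e.confidence:.2f}")
# The merged EGF -> ERK edge keeps min(0.9, 0.9) = 0.9: the cascade is only
# as believable as its weakest link.
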