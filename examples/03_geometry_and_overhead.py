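"""Print-geometry arithmetic and the security layer's byte overhead.

No training required — these are the protocol's closed-form numbers:
symbol sizes on paper, byte-mode capacities, and the exactly-2-byte
expansion added by encryption plus authentication.
"""

from qrstab import (
    CodecProfile,
    QRConfig,
    derive_nonce,
    encrypt,
    fingerprint,
    print_edge_cm,
    print_edge_inches,
    qr_capacity,
    qr_modules,
)

for version in (25, 40):
    cfg = QRConfig(version=version)
    print(f"version {version}: {qr_modules(version)}x{qr_modules(version)} "
          f"modules, {qr_capacity(version, 'L')} B at level L, "
          f"{print_edge_inches(cfg):.2f} in theoretical, "
          f"{print_edge_cm(cfg, with_redundancy=True):.2f} cm with 20% slack")

profile = CodecProfile(version=1, secret=bytes(range(32)))
plain = b"\x5a" * 1000
nonce = derive_nonce(profile, 1, 745, 1)
cipher = encrypt(plain, profile.secret, nonce)
tag = fingerprint(cipher, "patient-001", profile.fingerprint_len)
print(f"plaintext {len(plain)} B -> ciphertext {len(cipher)} B "
      f"(+{len(cipher) - len(plain)}), tag {len(tag)} B "
      f"=> total overhead {len(cipher) - len(plain) + len(tag)} B per packet")
print(f"false-accept probability of a random tag: 1/{2 ** (8 * len(tag))}")
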