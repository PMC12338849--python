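"""Compare the five compression pipelines on a synthetic record corpus.

Prints per-combination mean/median compression ratios (original minified
JSON bytes / compressed bytes — higher is better), paired-test p-values,
and how many QR symbols each record would need at the version-25/L
capacity of 1273 bytes.
"""

from qrstab import (
    CodecProfile,
    GeneratorProfile,
    generate_corpus,
    generate_records,
    qr_count_distribution,
    run_combos,
    train_tokenizer,
)

gen = GeneratorProfile(seed=7)
print("training tokenizer ...")
tokenizer = train_tokenizer(generate_corpus(gen, 1, 2000), "bpe", 3000)
profile = CodecProfile(version=1, secret=bytes(32), tokenizer=tokenizer)

records = generate_records(gen, 100)
result = run_combos(records, profile)

print(f"{'pipeline':<18}{'mean':>7}{'median':>8}{'min':>7}{'max':>7}")
for combo, s in result.summary().items():
    print(f"{combo:<18}{s['mean_ratio']:>7.2f}{s['median_ratio']:>8.2f}"
          f"{s['min_ratio']:>7.2f}{s['max_ratio']:>7.2f}")
for name, t in result.paired_tests().items():
    print(f"{name}: t={t['t']:.1f}, p={t['p']:.2g}")

dist = qr_count_distribution(result)
print("QR symbols per record:", dict(sorted(dist["histogram"].items())))
print(f"single-symbol share: {dist['cdf'].get(1, 0) * 100:.1f}%")
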