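# Demo run: simulate wild-type and figl1 F2 populations on a two-chromosome
# genome, build Kosambi maps and compare ~5 Mb super-intervals.
#   meiocross run --config examples/demo_config.yaml --out scratch/demo
chromosomes:
  - name: chr1
    length_mb: 30.0
    centromere_mb: [13.0, 16.0]
  - name: chr2
    length_mb: 20.0
    centromere_mb: [4.0, 7.0]
centromere_suppression: 0.05
spacing_mb: 1.5
n: 150
context: inbred
presets: [wild_type, figl1]
min_mb: 5.0
seed: 11
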