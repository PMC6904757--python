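Place the published iJA1121 genome-scale model of Bacillus megaterium DSM319
here as iJA1121.xml (SBML Level 3 + FBC). The file is distributed as
supplementary material of the reconstruction and is not redistributable with
this package. The two genome-scale acceptance tests in
tests/test_acceptance.py and the `megaflux stats` / `megaflux validate-growth`
examples use it when present; all other tests run on synthetic fixtures and
need no external files.
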