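# Examples

Short narrative scripts, one per capability. Each builds a small synthetic
input, runs one stage of the protocol, and prints what it computes.

| script | capability |
| --- | --- |
| `simulate_benchmark.py` | deterministic paired sequence/PSSM/image benchmark |
| `sequence_descriptors.py` | PseAAC, physicochemical-correlation and PSSM descriptors |
| `stain_unmixing.py` | optical-density stain separation, quality filter, patching |
| `texture_features.py` | Haralick, wavelet-Haralick, LBP, frozen embeddings |
| `feature_selection_demo.py` | LASSO and stepwise discriminant analysis recovery |
| `crossval_voting.py` | full five-voter cross-validated protocol (~30 s) |

Run from the repository root, e.g. `python examples/crossval_voting.py`.
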