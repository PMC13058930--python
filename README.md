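# ocsr — rule-based probabilistic optical chemical structure recognition

`ocsr` converts raster images of 2D chemical structure drawings into
molecular graphs and MDL Molfiles. It is aimed at cheminformatics and
drug-discovery pipelines that need to lift structures out of patents and
older literature, where the structure exists only as a picture.

The pipeline is rule-based and fully interpretable:

1. **Raster stage** — binarization (Otsu), border trimming, padding,
   nearest-neighbour upscaling of small images, Zhang–Suen thinning, and
   circle-Hough detection of aromatic-ring circles.
2. **Fragment-merging (FM) line detection** — a line Hough transform at
   deliberately fine resolution (2 px / 2°) shatters every stroke into short
   *fragments*; fragments that agree in angle, lie on each other's carrier
   line, and overlap or are bridged by ink are merged back into precise bond
   lines with union-find. This is adaptive to image scale and recovers
   broken strokes.
3. **Bond typing** — parallel line groups become double/triple bonds, long
   crossings are split at interior intersections, and dedicated detectors
   handle solid wedges (stroke-width profile), dashed lines/wedges (groups of
   ≥4 parallel short strokes, classified by length variance), wavy bonds
   (collinear runs of ≥3 long circular arcs) and aromatic circles.
4. **Symbols** — residual shapes are grouped into labels, split into
   mainline/superscript/subscript blocks, read by a pluggable OCR backend
   (a deterministic bitmap-template stub ships for hermetic testing; a
   Tesseract adapter is optional), and parsed into elements, hydrogen counts,
   charges, or superatom abbreviations (`Me`, `OTos`, …) from a shipped
   dictionary.
5. **Candidate resolution (the core)** — every bond ending spawns an *atom
   candidate* with bounding circle radius `r_b = min(l_bond, l_med)/4`;
   terminal label glyphs spawn candidates with bounding squares of side
   `sl_b = 1.5·max(sl_sym, sl_med)`. A Markov network over boolean
   existence and pairwise merge variables is scored with geometric rules
   (existence potential 0.9 for supported candidates; merge likelihood
   decaying 0.9 → 0.1 with center distance), MAP inference picks the most
   probable joint state, and candidates are merged by transitive closure
   into final atoms and bonds.
6. **Assembly** — the atoms/bonds become a graph, the largest connected
   component is kept, abbreviations are substituted by their substructures,
   and the result is written as a Molfile V2000.

## Worked example

```python
import numpy as np
from ocsr import fixtures, assemble

spec = fixtures.random_spec(8, seed=3)          # 8-atom molecule on a hex grid
fx = fixtures.render(spec)                      # binary image + ground truth
molfile = assemble.recognize(fx.image)
print(molfile)
```

prints (abridged):

```
  ocsr   2D

  8  8  0  0  0  0  0  0  0  0999 V2000
    0.4422    1.4591    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.1922    0.2304    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    ...
  1  2  1  0  0  0  0
  ...
M  END
```

i.e. an 8-atom, 8-bond connection table whose coordinates are normalized to
1.5 units per median bond length. `assemble.recognize_graph` returns the
in-memory `MoleculeGraph` instead, with per-atom elements, charges and
hydrogen counts.

The same functionality is available from the shell:

```bash
ocsr fixtures --n 10 --seed 7 --out demo/         # images + truth Molfiles
ocsr recognize demo/fixture_0000.png -o out.mol
ocsr eval --images demo --truth demo              # graph-isomorphism score
```

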