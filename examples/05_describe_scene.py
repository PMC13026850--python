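"""Turn a predicted mask into structured descriptors and a summary prompt.

Descriptors are computed from the mask and image only: per-class area
ratios, presence flags, whether an instrument touches the frame border, and
a variance-of-Laplacian blur score. The prompt builder is deterministic and
always appends a non-clinical disclaimer; any text backend can be plugged in
(here, a trivial echo backend).
"""

import frozenseg as fs

pair = fs.generate_scene(fs.SceneSpec.sinus_like(size=128), seed=11)

descriptors, prompt, summary = fs.summarize_scene(
    pair.image, pair.mask, ["background", "instrument"], fs.EchoBackend()
)
print("descriptors JSON:")
print(descriptors.to_json())
print("\nprompt sent to the backend:")
print(prompt)
print("\nbackend output:")
print(summary)
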