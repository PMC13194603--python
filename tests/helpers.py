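"""Shared test helpers."""

from mvct.networks import tiny_discriminator_spec, tiny_generator_spec
from mvct.stage1 import _build_model


def stub_model(view, add_l2h=0.0, add_h2l=0.0):
    """A translation model whose generators are exact identities (zeroed
    RED-CNN: the input shortcut is all that remains) plus an optional output
    bias, i.e. ``x + c`` in normalized units."""
    m = _build_model(view, tiny_generator_spec("redcnn"), tiny_discriminator_spec(), 0)
    for net, c in ((m.g_xy, add_l2h), (m.g_yx, add_h2l)):
        for mod, k in net.parameters():
            mod.params[k][:] = 0.0
        net.deconvs[-1].params["b"][:] = c
    return m
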