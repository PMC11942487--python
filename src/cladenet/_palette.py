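"""Ordered module color palette.

The conventional module-naming palette from weighted coexpression analysis:
modules are labeled by color names assigned in descending size order, with
"grey" reserved for unassigned genes (never part of the palette).
"""

GREY = "grey"

#: Ordered palette; index 0 names the largest module.
PALETTE: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lightpink4",
    "lavenderblush3", "honeydew1", "darkseagreen4", "coral1",
)


def color_name(rank: int) -> str:
    """Color name for the module of the given size rank (0 = largest).

    Beyond the palette, deterministic ``module<k>`` names are generated.
    """
    if rank < len(PALETTE):
        return PALETTE[rank]
    return f"module{rank}"
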