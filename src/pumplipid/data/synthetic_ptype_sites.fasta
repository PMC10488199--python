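>AHA2_SYN synthetic stand-in block around anionic-lipid contact sites
YRYWRHYKCMKYFNHLPFWQSMWDEDVRKVQARNSNVCTHADEP
>AHA1_SYN synthetic stand-in block around anionic-lipid contact sites
YRYWRHYKCMKYFNHLPFWQSMWDEDVCKVQARNSNDQTHADEP
>NpPMA2_SYN synthetic stand-in block around anionic-lipid contact sites
YRYARHYKIMKYFNHLPFWQSMWDEDVRKMQARCSNVCEHADEP
>OsPMA_SYN synthetic stand-in block around anionic-lipid contact sites
YRYWHHYKCMKYFNHLPGNQSMWDYDVRKVCARNSDVCTHADEP
>ScPMA1_SYN synthetic stand-in block around anionic-lipid contact sites
YSYWVDYKDMRYFNHEYFWQLMWDEDVGKVSARAVEVCTHAAEP
>NcPMA1_SYN synthetic stand-in block around anionic-lipid contact sites
GRPWRHYKCMKYNNLLPPTQSMWAEDVNKVQARHGNICPFTDQP
>SERCA_SYN synthetic stand-in block around anionic-lipid contact sites
YP--YEYKFTDYFHLDKNHQSYIDEDVRAVQARGSKPCTHAHEC
>NAK_SYN synthetic stand-in block around anionic-lipid contact sites
YRYTGMYHQFTEMNHVPFWYSITDEDERCVGAREGQVDTH--YN
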