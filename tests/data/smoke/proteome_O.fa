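>g0000t1_prot
MRPRDRHVFHRYKRRETGWHWRPSKKGEINQETFVHHDRFSWELLRLFTSVGLHLEGDRS
KALVKKVTQWGNRGPEERGHLNDRQGILQRLPPCPGQ
>g0000t2_prot
MRPRDRHVFHRYKRRETGWHWRPSKKGEINQETFVHHDRFSWELLRLFTSVGLHLEGDRS
KALVKKVTQWGNRGPEERGHLNDRQGILEVRSTPVFYSGQSNCYDELAVTG
>g0001t1_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRSFSKFYTVIEESNYQTTNKVWPFK
LCSVATRPLITSSCGMWYHPSLKDFDMLDTHGAYKHGQDLPFS
>g0001t2_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRPLITSSCGMWYHPSLKDFDMLDTH
GAYKHGQDLPFS
>g0001tG_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRSFSKFYTVIEESNYQTTNKVWPFK
LCSVATRVERTLREHRGSMLMSPLITSSCGMWYHPSLKDFDMLDTHGAYKHGQDLPFS
>g0002t1_prot
MRSVRLVGIMDAAELPLRAIHKLLAPNLLSRATYIGLCTQNYGNFSYLGLNRRHIPLLSL
ALSHQPARSEVIRQSELPRLEAVRGSRLARLPRPIAVMV
>g0002t2_prot
MRSVRLVGIMDAAELPLRAIHKLLAPNLLSRATYIGLCTQNYGNFSYLGLNRRHIPLLSL
ALSHQPARSEVIRQWLPCSYIRIHLKS
>g0004t1_prot
MPALRFRLSPKQYRRCGQVRVFVMKLRGGDMNAECTIARSYVMSVQHTSELSGLIVLMRG
DSVRYRAPNRAVRKTATPIYASEYPSASRVCLTAKFCLIKKCVFRCFSSDAQVL
>g0004t2_prot
MPALRFRLSPKQYRRCGQVRVFVMKLRGGDMNAECTIARSYVMSVQHTSELSGLIVLMRG
DSVRYRAPNRARCFSSDAQVL
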