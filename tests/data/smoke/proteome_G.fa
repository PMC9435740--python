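>g0000t1_prot
MRPRDRHVFHRYKRRETGWHWRPSKKGEINQETFLHHDRFSWELLRLFTSVGLHLEGDRS
KALVKKVTQWGNRGPEERGHLNDRQGILQRLPPCPGQ
>g0000t2_prot
MRPRDRHVFHRYKRRETGWHWRPSKKGEINQETFLHHDRFSWELLRLFTSVGLHLEGDRS
KALVKKVTQWGNRGPEERGHLNDRQGILEVRSTPVFYSGQSNCYDELAVTG
>g0001t1_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRSFSKFNTVIEESNYQTTIKVWPFK
LCSVATRPLITSSCGMWYHPSLKYFDMLDTHGAYKHGQDLPFS
>g0001t2_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRPLITSSCGMWYHPSLKYFDMLDTH
GAYKHGQDLPFS
>g0001tG_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRSFSKFNTVIEESNYQTTIKVWPFK
LCSVATRVERTLREHRGSMLMSPLITSSCGMWYHPSLKYFDMLDTHGAYKHGQDLPFS
>g0002t1_prot
MRSVRLVGIMDAAELPLRAIHKLLAPNLLSRATYIGLCTQNYGNFSYLGLNRRHIPLLSL
ALSHQPARSEVIRQSELPRLEAVRGSRLARLPRPIAVML
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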