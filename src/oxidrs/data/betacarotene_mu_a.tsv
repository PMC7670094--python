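# epidermal beta-carotene per unit fraction (1/mm), relative scale
# SYNTHETIC approximation; substitute your own table for exact literature curves.
# wavelength_nm	mu_a_per_mm
450	30.3682
452	30.739
454	30.145
456	28.7958
458	27.0134
460	25.1745
462	23.639
464	22.6823
466	22.4438
468	22.9028
470	23.8867
472	25.1081
474	26.2235
476	26.9013
478	26.8836
480	26.0308
482	24.339
484	21.9301
486	19.0181
488	15.8624
490	12.7192
492	9.80233
494	7.25967
496	5.16636
498	3.53273
500	2.32104
502	1.46518
504	0.888662
506	0.517861
508	0.289947
510	0.155975
512	0.0806157
514	0.0400325
516	0.0191001
518	0.00875558
520	0.00385623
522	0.00163181
524	0.000663445
526	0.00025916
528	9.72657e-05
530	3.50735e-05
532	1.21514e-05
534	4.04486e-06
536	1.29362e-06
538	3.97502e-07
540	1.17355e-07
542	3.32881e-08
544	9.07208e-09
546	2.37548e-09
548	5.97621e-10
550	1.44453e-10
552	3.35473e-11
554	7.48541e-12
556	1.60473e-12
558	0
560	0
562	0
564	0
566	0
568	0
570	0
572	0
574	0
576	0
578	0
580	0
582	0
584	0
586	0
588	0
590	0
592	0
594	0
596	0
598	0
600	0
602	0
604	0
606	0
608	0
610	0
612	0
614	0
616	0
618	0
620	0
622	0
624	0
626	0
628	0
630	0
632	0
634	0
636	0
638	0
640	0
642	0
644	0
646	0
648	0
650	0
652	0
654	0
656	0
658	0
660	0
662	0
664	0
666	0
668	0
670	0
672	0
674	0
676	0
678	0
680	0
682	0
684	0
686	0
688	0
690	0
692	0
694	0
696	0
698	0
700	0
702	0
704	0
706	0
708	0
710	0
712	0
714	0
716	0
718	0
720	0
722	0
724	0
726	0
728	0
730	0
732	0
734	0
736	0
738	0
740	0
742	0
744	0
746	0
748	0
750	0
752	0
754	0
756	0
758	0
760	0
762	0
764	0
766	0
768	0
770	0
772	0
774	0
776	0
778	0
780	0
782	0
784	0
786	0
788	0
790	0
792	0
794	0
796	0
798	0
800	0
802	0
804	0
806	0
808	0
810	0
812	0
814	0
816	0
818	0
820	0
822	0
824	0
826	0
828	0
830	0
832	0
834	0
836	0
838	0
840	0
842	0
844	0
846	0
848	0
850	0
852	0
854	0
856	0
858	0
860	0
862	0
864	0
866	0
868	0
870	0
872	0
874	0
876	0
878	0
880	0
882	0
884	0
886	0
888	0
890	0
892	0
894	0
896	0
898	0
900	0
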